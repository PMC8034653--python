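"""Readers and writers for the standard formats the pipeline touches.

Coordinate convention: positions are 1-based and inclusive everywhere in the
public API, matching CT files and rRNA residue numbering.  SAM's native
1-based alignment starts pass through unchanged.  Internally, numpy arrays
indexed from 0 carry an unused slot 0 where that simplifies bookkeeping
(pair tables), and this is never exposed.

Supported formats: FASTA, dot-bracket (optional FASTA-like header), CT
(6-column connectivity table), SAM (text), PDB, and tab-delimited
reactivity / mutation-profile tables.
"""

from __future__ import annotations

import io
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceStructure",
    "ResidueCoordinates",
    "PdbAtom",
    "AlignedRead",
    "StructureParseError",
    "read_dotbracket",
    "write_dotbracket",
    "read_ct",
    "write_ct",
    "read_fasta",
    "write_fasta",
    "read_sam",
    "write_sam",
    "read_pdb_residues",
    "read_reactivity_table",
    "write_reactivity_table",
    "read_profile_table",
    "write_profile_table",
    "VDW_RADII",
]


class StructureParseError(ValueError):
    """Raised for malformed secondary-structure input (position is 1-based)."""


# Bracket layers in conventional precedence order: the primary "()" layer,
# then square/curly/angle brackets, then letter pairs Aa, Bb, ... for
# higher-order pseudoknots.  Uppercase opens, lowercase closes.
_LAYERS: list[tuple[str, str]] = (
    [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]
    + [(chr(ord("A") + k), chr(ord("a") + k)) for k in range(26)]
)
_OPEN = {o: i for i, (o, _) in enumerate(_LAYERS)}
_CLOSE = {c: i for i, (_, c) in enumerate(_LAYERS)}


def _as_text(source) -> str:
    """Accept a path, an open file object, or raw text content."""
    if hasattr(source, "read"):
        return source.read()
    source = os.fspath(source) if isinstance(source, os.PathLike) else source
    if isinstance(source, str) and "\n" not in source and os.path.exists(source):
        with open(source) as fh:
            return fh.read()
    return source


@dataclass
class ReferenceStructure:
    """An RNA sequence with its known base-pairing.

    ``pair_table`` has length n+1; entry ``i`` (1-based) holds the partner
    of position ``i`` or 0 if unpaired; entry 0 is unused.  Ground truth for
    all downstream evaluation.
    """

    id: str
    sequence: str
    pair_table: np.ndarray
    dotbracket: str = ""

    def __post_init__(self):
        self.pair_table = np.asarray(self.pair_table, dtype=np.int32)
        if len(self.pair_table) != len(self.sequence) + 1:
            raise StructureParseError(
                f"pair table length {len(self.pair_table)} does not match "
                f"sequence length {len(self.sequence)} + 1"
            )
        self._validate()
        if not self.dotbracket:
            self.dotbracket = encode_dotbracket(self.pair_table)

    def _validate(self) -> None:
        pt = self.pair_table
        for i in range(1, len(pt)):
            j = int(pt[i])
            if j == 0:
                continue
            if j == i:
                raise StructureParseError(f"position {i} pairs with itself")
            if not (1 <= j < len(pt)) or int(pt[j]) != i:
                raise StructureParseError(
                    f"asymmetric pair table: {i} -> {j} but {j} -> {pt[j] if 1 <= j < len(pt) else '?'}"
                )

    @property
    def n(self) -> int:
        return len(self.sequence)

    def pairs(self) -> list[tuple[int, int]]:
        """All base pairs as (i, j) with i < j, 1-based, sorted by i."""
        pt = self.pair_table
        return [(i, int(pt[i])) for i in range(1, len(pt)) if pt[i] > i]

    @property
    def fraction_paired(self) -> float:
        return float(np.count_nonzero(self.pair_table[1:]) / self.n)

    @classmethod
    def from_pairs(cls, id: str, sequence: str, pairs) -> "ReferenceStructure":
        pt = np.zeros(len(sequence) + 1, dtype=np.int32)
        for i, j in pairs:
            pt[i], pt[j] = j, i
        return cls(id=id, sequence=sequence, pair_table=pt)


def decode_dotbracket(structure: str) -> np.ndarray:
    """Decode a dot-bracket string into a 1-based pair table.

    Each bracket type is decoded with its own stack, so crossing
    (pseudoknotted) pairs are supported as long as each layer is
    individually nested.
    """
    n = len(structure)
    pt = np.zeros(n + 1, dtype=np.int32)
    stacks: dict[int, list[int]] = {}
    for pos0, ch in enumerate(structure):
        pos = pos0 + 1
        if ch == ".":
            continue
        if ch in _OPEN:
            stacks.setdefault(_OPEN[ch], []).append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE[ch]
            if not stacks.get(layer):
                raise StructureParseError(
                    f"unbalanced bracket '{ch}' at position {pos}: no matching opener"
                )
            i = stacks[layer].pop()
            pt[i], pt[pos] = pos, i
        else:
            raise StructureParseError(f"unknown structure character '{ch}' at position {pos}")
    for layer, stack in stacks.items():
        if stack:
            o = _LAYERS[layer][0]
            raise StructureParseError(
                f"unbalanced bracket '{o}' at position {stack[-1]}: never closed"
            )
    return pt


def encode_dotbracket(pair_table: np.ndarray) -> str:
    """Encode a pair table as dot-bracket, assigning crossing pairs to
    successive bracket layers greedily (first layer where the pair does not
    cross any pair already in that layer)."""
    n = len(pair_table) - 1
    chars = ["."] * n
    layer_pairs: list[list[tuple[int, int]]] = []
    pairs = [(i, int(pair_table[i])) for i in range(1, n + 1) if pair_table[i] > i]
    for i, j in pairs:
        placed = False
        for layer, existing in enumerate(layer_pairs):
            if all(not (a < i < b < j or i < a < j < b) for a, b in existing):
                existing.append((i, j))
                o, c = _LAYERS[layer]
                chars[i - 1], chars[j - 1] = o, c
                placed = True
                break
        if not placed:
            layer = len(layer_pairs)
            if layer >= len(_LAYERS):
                raise StructureParseError("structure requires more pseudoknot layers than supported")
            layer_pairs.append([(i, j)])
            o, c = _LAYERS[layer]
            chars[i - 1], chars[j - 1] = o, c
    return "".join(chars)


def strip_pseudoknot_pairs(structure: ReferenceStructure) -> ReferenceStructure:
    """Drop every pair not encoded in the primary '()' layer."""
    keep = [
        (i, j)
        for i, j in structure.pairs()
        if structure.dotbracket[i - 1] == "(" and structure.dotbracket[j - 1] == ")"
    ]
    return ReferenceStructure.from_pairs(structure.id, structure.sequence, keep)


def read_dotbracket(source, strip_pseudoknots: bool = False) -> ReferenceStructure:
    """Parse dot-bracket text: optional '>' header, sequence line, structure line."""
    lines = [ln.strip() for ln in _as_text(source).splitlines() if ln.strip()]
    name = "structure"
    if lines and lines[0].startswith(">"):
        name = lines[0][1:].split()[0] if lines[0][1:].split() else "structure"
        lines = lines[1:]
    if len(lines) < 2:
        raise StructureParseError("expected a sequence line and a structure line")
    sequence, structure = lines[0].upper().replace("T", "U"), lines[1]
    if len(sequence) != len(structure):
        raise StructureParseError(
            f"sequence length {len(sequence)} != structure length {len(structure)}"
        )
    pt = decode_dotbracket(structure)
    ref = ReferenceStructure(id=name, sequence=sequence, pair_table=pt, dotbracket=structure)
    if strip_pseudoknots:
        ref = strip_pseudoknot_pairs(ref)
    return ref


def write_dotbracket(structure: ReferenceStructure) -> str:
    return f">{structure.id}\n{structure.sequence}\n{structure.dotbracket}\n"


def read_ct(source) -> ReferenceStructure:
    """Parse a standard 6-column connectivity table (CT) file."""
    lines = [ln for ln in _as_text(source).splitlines() if ln.strip()]
    if not lines:
        raise StructureParseError("empty CT file")
    header = lines[0].split()
    try:
        n = int(header[0])
    except (ValueError, IndexError):
        raise StructureParseError(f"malformed CT header: {lines[0]!r}")
    name = header[1] if len(header) > 1 else "structure"
    if len(lines) - 1 < n:
        raise StructureParseError(f"CT header declares {n} rows, found {len(lines) - 1}")
    seq = []
    pt = np.zeros(n + 1, dtype=np.int32)
    for row in lines[1 : n + 1]:
        cols = row.split()
        if len(cols) < 6:
            raise StructureParseError(f"CT row has fewer than 6 columns: {row!r}")
        i, base, partner = int(cols[0]), cols[1], int(cols[4])
        if not (1 <= i <= n):
            raise StructureParseError(f"CT row index {i} out of range 1..{n}")
        seq.append(base.upper().replace("T", "U"))
        pt[i] = partner
    for i in range(1, n + 1):
        j = int(pt[i])
        if j and (not (1 <= j <= n) or int(pt[j]) != i or j == i):
            raise StructureParseError(f"asymmetric CT pairing: row {i} claims partner {j}")
    return ReferenceStructure(id=name, sequence="".join(seq), pair_table=pt)


def write_ct(structure: ReferenceStructure) -> str:
    out = [f"{structure.n} {structure.id}"]
    for i in range(1, structure.n + 1):
        out.append(
            f"{i} {structure.sequence[i - 1]} {i - 1} {(i + 1) % (structure.n + 1)} "
            f"{int(structure.pair_table[i])} {i}"
        )
    return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(source) -> dict[str, str]:
    """Parse FASTA; returns an insertion-ordered {id: sequence} mapping."""
    from Bio import SeqIO

    text = _as_text(source)
    records = {}
    for rec in SeqIO.parse(io.StringIO(text), "fasta"):
        records[rec.id] = str(rec.seq).upper()
    if not records:
        raise ValueError("no FASTA records found")
    return records


def write_fasta(sequences: dict[str, str]) -> str:
    return "".join(f">{name}\n{seq}\n" for name, seq in sequences.items())


# ---------------------------------------------------------------------------
# SAM

@dataclass
class AlignedRead:
    """The subset of a SAM record the counting pipeline needs."""

    qname: str
    flag: int
    rname: str
    pos: int  # 1-based leftmost aligned reference position
    mapq: int
    cigar: list[tuple[str, int]]
    seq: str
    qual: np.ndarray  # Phred scores, uint8, one per SEQ base

    @property
    def is_mapped(self) -> bool:
        return not self.flag & 0x4

    @property
    def is_primary(self) -> bool:
        return not self.flag & (0x100 | 0x800)

    def reference_span(self) -> int:
        """Number of reference positions consumed by the alignment."""
        return sum(length for op, length in self.cigar if op in "MDN=X")


_CIGAR_OPS = "MIDNSHP=X"


def _parse_cigar(cig: str) -> list[tuple[str, int]]:
    out, num = [], ""
    for ch in cig:
        if ch.isdigit():
            num += ch
        elif ch in _CIGAR_OPS and num:
            out.append((ch, int(num)))
            num = ""
        else:
            raise ValueError(f"malformed CIGAR {cig!r}")
    if num:
        raise ValueError(f"malformed CIGAR {cig!r}")
    return out


def read_sam(source) -> list[AlignedRead]:
    """Parse text SAM into :class:`AlignedRead` records.

    Records whose CIGAR-implied read length disagrees with SEQ are skipped
    and counted in a single log message, per-record errors never abort the
    parse.  Unmapped records are kept here (so drop statistics can be
    reported) and excluded later by the counting step.
    """
    reads, skipped = [], 0
    for line in _as_text(source).splitlines():
        if not line.strip() or line.startswith("@"):
            continue
        f = line.rstrip("\n").split("\t")
        if len(f) < 11:
            skipped += 1
            continue
        try:
            flag, pos, mapq = int(f[1]), int(f[3]), int(f[4])
            cigar = _parse_cigar(f[5]) if f[5] != "*" else []
            seq = f[9] if f[9] != "*" else ""
            if cigar:
                implied = sum(n for op, n in cigar if op in "MIS=X")
                if implied != len(seq):
                    raise ValueError("CIGAR/SEQ length mismatch")
            if f[10] == "*" or not seq:
                qual = np.full(len(seq), 255, dtype=np.uint8)
            else:
                qual = np.frombuffer(f[10].encode(), dtype=np.uint8) - 33
                if len(qual) != len(seq):
                    raise ValueError("QUAL/SEQ length mismatch")
        except ValueError:
            skipped += 1
            continue
        reads.append(
            AlignedRead(qname=f[0], flag=flag, rname=f[2], pos=pos, mapq=mapq,
                        cigar=cigar, seq=seq, qual=qual)
        )
    if skipped:
        logger.warning("read_sam: skipped %d malformed record(s)", skipped)
    return reads


def write_sam(reads, reference_name: str, reference_length: int) -> str:
    """Serialise reads as text SAM with a minimal header."""
    lines = ["@HD\tVN:1.6\tSO:unsorted",
             f"@SQ\tSN:{reference_name}\tLN:{reference_length}"]
    for r in reads:
        cig = "".join(f"{n}{op}" for op, n in r.cigar) if r.cigar else "*"
        qual = "".join(chr(q + 33) for q in r.qual) if len(r.qual) else "*"
        lines.append(
            f"{r.qname}\t{r.flag}\t{r.rname}\t{r.pos}\t{r.mapq}\t{cig}\t*\t0\t0\t{r.seq}\t{qual}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# PDB

# Van der Waals radii (Å) after Bondi (1964), the standard single-element
# table; frozen here so SASA values are reproducible across environments.
VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "F": 1.47, "P": 1.80,
    "S": 1.80, "CL": 1.75, "BR": 1.85, "I": 1.98, "SE": 1.90,
    "MG": 1.73, "NA": 2.27, "K": 2.75, "ZN": 1.39, "MN": 1.73, "FE": 1.63,
}
_DEFAULT_RADIUS = 1.50  # fallback for elements absent from the table

_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class PdbAtom:
    element: str
    x: float
    y: float
    z: float
    radius: float


@dataclass
class ResidueCoordinates:
    """Atoms of one residue, with van der Waals radii attached."""

    chain: str
    resnum: int
    resname: str = ""
    atoms: list[PdbAtom] = field(default_factory=list)

    def coords(self) -> np.ndarray:
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)


def read_pdb_residues(source, radius_table: dict[str, float] | None = None,
                      include_waters: bool = False) -> list[ResidueCoordinates]:
    """Parse ATOM/HETATM records into per-residue atom lists.

    Waters are excluded by default.  For alternate locations the
    highest-occupancy conformer is kept (ties: first encountered, which is
    Biopython's disordered-atom selection rule).  Residues are returned
    ordered by (chain, residue number).
    """
    import warnings

    from Bio.PDB import PDBParser
    from Bio.PDB.PDBExceptions import PDBConstructionWarning

    radius_table = radius_table if radius_table is not None else VDW_RADII
    text = _as_text(source)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", PDBConstructionWarning)
        parser = PDBParser(QUIET=True)
        model = parser.get_structure("pdb", io.StringIO(text))
    residues: list[ResidueCoordinates] = []
    for chain in sorted(model.get_chains(), key=lambda c: c.id):
        for res in chain:
            if not include_waters and res.get_resname().strip() in _WATER_RESNAMES:
                continue
            atoms = []
            for atom in res:  # disordered atoms yield their selected child
                el = (atom.element or atom.get_name()[:1]).strip().upper()
                r = radius_table.get(el, _DEFAULT_RADIUS)
                x, y, z = atom.coord
                atoms.append(PdbAtom(element=el, x=float(x), y=float(y), z=float(z), radius=r))
            if atoms:
                residues.append(
                    ResidueCoordinates(chain=chain.id, resnum=res.id[1],
                                       resname=res.get_resname().strip(), atoms=atoms)
                )
    if not residues:
        raise ValueError("no ATOM records found in PDB input")
    residues.sort(key=lambda r: (r.chain, r.resnum))
    return residues


# ---------------------------------------------------------------------------
# Tab-delimited tables

def write_reactivity_table(positions, bases, values) -> str:
    """Tab-delimited position / base / reactivity table; missing -> 'NaN'."""
    df = pd.DataFrame({"position": positions, "base": list(bases), "reactivity": values})
    return df.to_csv(sep="\t", index=False, na_rep="NaN", float_format="%.6f")


def read_reactivity_table(source) -> pd.DataFrame:
    df = pd.read_csv(io.StringIO(_as_text(source)), sep="\t", na_values=["NaN", "nan"])
    required = {"position", "base", "reactivity"}
    if not required.issubset(df.columns):
        raise ValueError(f"reactivity table must have columns {sorted(required)}")
    return df


def write_profile_table(profile) -> str:
    """Serialise a MutationProfile as position/refbase/mutations/coverage/frequency."""
    freq = profile.frequency
    df = pd.DataFrame({
        "position": np.arange(1, profile.n + 1),
        "refbase": list(profile.sequence),
        "mutations": profile.counts,
        "coverage": profile.coverage,
        "frequency": freq,
    })
    return df.to_csv(sep="\t", index=False, na_rep="NaN", float_format="%.8f")


def read_profile_table(source, transcript_id: str = "profile", min_coverage: int = 100):
    from .counting import MutationProfile

    df = pd.read_csv(io.StringIO(_as_text(source)), sep="\t", na_values=["NaN", "nan"])
    return MutationProfile(
        transcript_id=transcript_id,
        sequence="".join(df["refbase"].astype(str)),
        counts=df["mutations"].to_numpy(dtype=np.int64),
        coverage=df["coverage"].to_numpy(dtype=np.int64),
        min_coverage=min_coverage,
    )
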