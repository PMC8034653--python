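"""Ground-truthed synthetic data: structures, reagent-like modification
rates, and mutational-profiling reads.

The generator emulates what a MaP experiment measures: a treated channel
whose per-base modification rate is high on flexible (unpaired) bases
and low on stem bases, and a control (DMSO) channel carrying only the
sequencing/RT error floor.  A reagent preset fixes the rate
distributions; the presets' loop/stem contrasts target the
signal-to-noise regimes of a high-performing membrane-permeable SHAPE
reagent ("2A3-like", S/N ~ 3.5), a poorly permeable one ("NAI-like",
S/N ~ 1.3, modelled as the same intrinsic chemistry scaled by a small
permeability factor), and a pure background control ("DMSO").

Everything is deterministic per seed: the same (seed, model, structure,
n_reads) regenerates reads bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernels
from .counting import ReadBatch
from .formats import ReferenceStructure
from .structure_stats import extract_hairpins

__all__ = [
    "ReagentModel",
    "SyntheticExperiment",
    "REAGENT_PRESETS",
    "get_reagent",
    "sample_structure",
    "assign_rates",
    "simulate_reads",
    "simulate_experiment",
]


@dataclass(frozen=True)
class ReagentModel:
    """Per-read, per-base modification model for one probing reagent.

    Unpaired bases draw their modification probability from a gamma
    distribution and paired bases from an exponential (heavier mass near
    zero); both are scaled by a membrane-permeability factor in (0, 1]
    and offset by the background error rate ``error_rate``, which is the
    only signal in the control channel.
    """

    name: str
    unpaired_shape: float = 4.0
    unpaired_scale: float = 0.004
    paired_mean: float = 0.004
    error_rate: float = 0.002
    permeability: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.permeability <= 1.0):
            raise ValueError("permeability must lie in (0, 1]")
        if not (0.0 <= self.error_rate < 1.0):
            raise ValueError("error rate must lie in [0, 1)")

    @property
    def median_unpaired_rate(self) -> float:
        return float(stats.gamma.ppf(0.5, self.unpaired_shape,
                                     scale=self.unpaired_scale)) * self.permeability

    @property
    def median_paired_rate(self) -> float:
        return float(stats.expon.ppf(0.5, scale=self.paired_mean)) * self.permeability

    @property
    def expected_snr(self) -> float:
        """Loop/stem frequency ratio implied by the distribution medians."""
        return ((self.median_unpaired_rate + self.error_rate)
                / (self.median_paired_rate + self.error_rate))


REAGENT_PRESETS: dict[str, ReagentModel] = {
    # fully permeable, strong loop/stem contrast: S/N ~ 3.5
    "2A3-like": ReagentModel(name="2A3-like", permeability=1.0),
    # same chemistry, barely crosses the membrane: S/N ~ 1.3
    "NAI-like": ReagentModel(name="NAI-like", permeability=0.05),
    # control channel only: background error floor
    "DMSO": ReagentModel(name="DMSO", permeability=0.0),
}


def get_reagent(name_or_model) -> ReagentModel:
    if isinstance(name_or_model, ReagentModel):
        return name_or_model
    try:
        return REAGENT_PRESETS[name_or_model]
    except KeyError:
        raise KeyError(f"unknown reagent preset {name_or_model!r}; "
                       f"choose from {sorted(REAGENT_PRESETS)}")


# ---------------------------------------------------------------------------
# Structure sampling

_PAIR_CHOICES = [("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")]
_PAIR_WEIGHTS = np.array([0.28, 0.28, 0.17, 0.17, 0.05, 0.05])
_UNPAIRED_CHOICES = np.array(list("ACGU"))


def sample_structure(length: int, seed: int, helix_len_range=(3, 8),
                     loop_len_range=(3, 8),
                     structure_id: str | None = None) -> ReferenceStructure:
    """Sample a pseudoknot-free nested structure with a random sequence.

    Built by left-to-right placement of stem-loops (helix and loop lengths
    uniform over the given ranges) separated by short single-stranded
    spacers, with larger regions recursively nesting further elements.
    Every innermost stem-loop has >= 3 stacked pairs closing a loop of
    >= 3 nt, so at least one hairpin satisfying the loop/stem statistic's
    pattern is always present.  Deterministic per seed.
    """
    hmin, hmax = helix_len_range
    lmin, lmax = loop_len_range
    if hmin < 3 or lmin < 3:
        raise ValueError("helix and loop minima must be >= 3 to guarantee a hairpin")
    min_sl = 2 * hmin + lmin
    if length < min_sl + 2 * 3:
        raise ValueError(f"length must be >= {min_sl + 6} for these ranges")
    rng = np.random.default_rng(seed)

    def fill(L: int, depth: int) -> str:
        if L < min_sl:
            return "." * L
        out = []
        remaining = L
        first = True
        while remaining >= min_sl:
            spacer = 0 if first else int(rng.integers(1, 4))
            if remaining - spacer < min_sl:
                break
            first = False
            out.append("." * spacer)
            remaining -= spacer
            h = int(rng.integers(hmin, min(hmax, (remaining - lmin) // 2) + 1))
            interior_budget = remaining - 2 * h
            if depth < 4 and interior_budget >= min_sl + 2 and rng.random() < 0.5:
                interior_len = int(rng.integers(min_sl, interior_budget + 1))
                interior = fill(interior_len, depth + 1)
                if set(interior) == {"."} and len(interior) > lmax:
                    interior = "." * int(rng.integers(lmin, lmax + 1))
            else:
                interior = "." * int(rng.integers(lmin, min(lmax, interior_budget) + 1))
            used = 2 * h + len(interior)
            out.append("(" * h + interior + ")" * h)
            remaining -= used
        out.append("." * remaining)
        return "".join(out)

    db = fill(length, 0)
    from .formats import decode_dotbracket

    pt = decode_dotbracket(db)
    # complementary sequence assignment
    seq = [""] * length
    for i in range(1, length + 1):
        j = int(pt[i])
        if j == 0:
            seq[i - 1] = str(rng.choice(_UNPAIRED_CHOICES))
        elif j > i:
            a, b = _PAIR_CHOICES[int(rng.choice(len(_PAIR_CHOICES), p=_PAIR_WEIGHTS))]
            seq[i - 1], seq[j - 1] = a, b
    structure = ReferenceStructure(
        id=structure_id or f"synthetic_{length}nt_seed{seed}",
        sequence="".join(seq), pair_table=pt, dotbracket=db)
    if not extract_hairpins(structure):
        raise RuntimeError("generated structure lacks a hairpin (generator bug)")
    return structure


# ---------------------------------------------------------------------------
# Rates and reads

def assign_rates(structure: ReferenceStructure, reagent, seed: int):
    """Draw true per-base modification rates for the treated channel.

    Unpaired bases: gamma draw * permeability + error_rate; paired bases:
    exponential draw * permeability + error_rate; capped at 1.  Returns
    (rates, error_rate); the control channel's rate is error_rate
    everywhere.
    """
    reagent = get_reagent(reagent)
    rng = np.random.default_rng(seed)
    n = structure.n
    unpaired = structure.pair_table[1:] == 0
    rates = np.empty(n)
    rates[unpaired] = rng.gamma(reagent.unpaired_shape, reagent.unpaired_scale,
                                size=int(unpaired.sum()))
    rates[~unpaired] = rng.exponential(reagent.paired_mean,
                                       size=int((~unpaired).sum()))
    rates = np.clip(rates * reagent.permeability + reagent.error_rate, 0.0, 1.0)
    return rates, reagent.error_rate


_BASE_CODE_TABLE = np.full(256, 255, dtype=np.uint8)
for _k, _c in enumerate("ACGU"):
    _BASE_CODE_TABLE[ord(_c)] = _k
_CODE_BASE_TABLE = np.frombuffer(b"ACGU", dtype=np.uint8).copy()


def simulate_reads(structure: ReferenceStructure, rates, n_reads: int,
                   read_length: int, seed: int, rname: str | None = None,
                   qual: int = 37) -> ReadBatch:
    """Simulate aligned MaP reads with uniform random starts.

    Per covered base an independent Bernoulli(rate) decides modification;
    a modification is realized as a mismatch to a random non-reference
    base (probability 2/3) or a single-base deletion (1/3) — the split is
    arbitrary but fixed, and exercises both counting paths.  Base
    qualities are constant.  Bit-identical output per seed.
    """
    n = structure.n
    if read_length > n:
        raise ValueError("read_length exceeds the reference length")
    rates = np.asarray(rates, dtype=float)
    rng = np.random.default_rng(seed)
    starts = rng.integers(0, n - read_length + 1, size=n_reads)
    window = starts[:, None] + np.arange(read_length)[None, :]
    hit = rng.random((n_reads, read_length)) < rates[window]
    # realize events: 1..3 = mismatch offset, 4 = deletion
    mut = np.zeros((n_reads, read_length), dtype=np.int8)
    n_hit = int(hit.sum())
    kinds = rng.random(n_hit)
    offsets = rng.integers(1, 4, size=n_hit).astype(np.int8)
    mut[hit] = np.where(kinds < 2.0 / 3.0, offsets, np.int8(4))
    ref = np.frombuffer(structure.sequence.encode(), dtype=np.uint8)
    out_starts, seqs, seq_off, cig_ops, cig_lens, cig_off = \
        _kernels.assemble_reads_kernel(ref, starts.astype(np.int64), mut,
                                       _BASE_CODE_TABLE, _CODE_BASE_TABLE)
    return ReadBatch(
        rname=rname or structure.id, reference_length=n, starts=out_starts,
        seqs=seqs, seq_off=seq_off, cig_ops=cig_ops, cig_lens=cig_lens,
        cig_off=cig_off, quals=np.full(len(seqs), qual, dtype=np.uint8))


@dataclass
class SyntheticExperiment:
    """One simulated probing experiment: structure, true rates, and the
    treated / control read sets, all regenerable from the seed."""

    structure: ReferenceStructure
    rates: np.ndarray
    error_rate: float
    treated: ReadBatch
    control: ReadBatch
    seed: int
    reagent: ReagentModel


def simulate_experiment(seed: int, reagent="2A3-like", length: int = 300,
                        n_reads: int = 50_000, read_length: int = 150,
                        structure: ReferenceStructure | None = None) -> SyntheticExperiment:
    """Full treated + control experiment from a single seed.

    Sub-seeds for the structure, the rate draw and the two read channels
    are derived deterministically from ``seed``.
    """
    reagent = get_reagent(reagent)
    ss = np.random.SeedSequence(seed)
    s_struct, s_rates, s_treated, s_control = [
        int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(4)]
    if structure is None:
        structure = sample_structure(length, s_struct)
    rates, e = assign_rates(structure, reagent, s_rates)
    treated = simulate_reads(structure, rates, n_reads, read_length, s_treated)
    control = simulate_reads(structure, np.full(structure.n, e), n_reads,
                             read_length, s_control)
    return SyntheticExperiment(structure=structure, rates=rates, error_rate=e,
                               treated=treated, control=control, seed=seed,
                               reagent=reagent)
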