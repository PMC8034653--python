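"""Pseudo-free-energy restrained folding and prediction scoring.

Probing reactivities enter thermodynamic structure prediction as a
per-nucleotide pseudo-free-energy term

    dG(i) = m * ln(r_i + 1) + b    [kcal/mol]

charged to both partners of every formed pair, so a reactive (flexible)
base pays an energetic penalty for pairing.  The slope ``m`` and
intercept ``b`` are empirical; a grid search against reference
structures (jackknifing) selects them, scoring each (m, b) cell by the
geometric mean of the prediction's PPV and sensitivity under the relaxed
pair comparison (a predicted pair i/j is correct if the reference
contains i/j, i-1/j, i+1/j, i/j-1 or i/j+1).

Folding goes through a pluggable engine contract.  The built-in engine
is a deterministic dynamic program over a simplified stacking/loop
energy model (stacked Watson-Crick/wobble pairs, single-base bulges,
1x1 internal loops, multiloops); it is self-contained and fast, which is
what the evaluation machinery and test suite need.  An adapter to the
ViennaRNA nearest-neighbor engine is provided for thermodynamically realistic
thermodynamic predictions when the bindings are installed.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .formats import ReferenceStructure
from .reactivity import ReactivityProfile

__all__ = [
    "PseudoEnergyParams",
    "PredictionScore",
    "SlopeInterceptGrid",
    "FoldingError",
    "BuiltinEngine",
    "ViennaRNAEngine",
    "pseudo_energy",
    "fold",
    "relaxed_compare",
    "grid_search",
]


class FoldingError(RuntimeError):
    pass


@dataclass(frozen=True)
class PseudoEnergyParams:
    """Slope (kcal/mol per ln-unit of reactivity) and intercept (kcal/mol)."""

    m: float
    b: float


def pseudo_energy(reactivities, params: PseudoEnergyParams) -> np.ndarray:
    """Per-base restraint energies m*ln(r+1)+b; missing (NaN) -> NaN
    (the engine applies no term there)."""
    values = (reactivities.values if isinstance(reactivities, ReactivityProfile)
              else np.asarray(reactivities, dtype=float))
    defined = ~np.isnan(values)
    if np.any(values[defined] < 0):
        raise ValueError("reactivities must be non-negative (clip before folding)")
    out = np.full_like(values, np.nan, dtype=float)
    out[defined] = params.m * np.log(values[defined] + 1.0) + params.b
    return out


# ---------------------------------------------------------------------------
# Engines

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}

# Simplified pairing energies (kcal/mol): Watson-Crick and wobble pairs,
# with a bonus for helix continuation and penalties for loop openings.
_PAIR_E = np.full((4, 4), _kernels._INF)
for _a, _b, _e in [("G", "C", -3.0), ("C", "G", -3.0), ("A", "U", -2.0),
                   ("U", "A", -2.0), ("G", "U", -1.0), ("U", "G", -1.0)]:
    _PAIR_E[_BASE_CODE[_a], _BASE_CODE[_b]] = _e
_E_STACK = -1.5
_E_HAIRPIN = 3.5
_E_BULGE = 3.0
_E_INT11 = 2.5
_E_MULTI = 4.0


def _remove_lonely_pairs(pairs: set[tuple[int, int]]) -> set[tuple[int, int]]:
    """Iteratively drop pairs with no stacked neighbor on either side."""
    pairs = set(pairs)
    while True:
        lonely = {(i, j) for i, j in pairs
                  if (i + 1, j - 1) not in pairs and (i - 1, j + 1) not in pairs}
        if not lonely:
            return pairs
        pairs -= lonely


class BuiltinEngine:
    """Deterministic minimum-energy folder over a simplified nested model."""

    name = "builtin"

    def fold(self, sequence: str, penalties: np.ndarray,
             max_pair_distance: int = 600,
             allow_lonely_pairs: bool = False) -> set[tuple[int, int]]:
        n = len(sequence)
        codes = np.array([_BASE_CODE.get(c, -1) for c in sequence.upper()],
                         dtype=np.int8)
        pen = np.nan_to_num(np.asarray(penalties, dtype=float), nan=0.0)
        if len(pen) != n:
            raise FoldingError("penalty vector length does not match sequence")
        V, Vc, Vk, WMc, WMk, ptr = _kernels.fold_fill(
            codes, pen, max_pair_distance, _PAIR_E, _E_STACK, _E_HAIRPIN,
            _E_BULGE, _E_INT11, _E_MULTI)
        pairs: set[tuple[int, int]] = set()
        j = n - 1
        stack: list[tuple[str, int, int]] = []
        while j >= 0:
            i = int(ptr[j])
            if i == -1:
                j -= 1
                continue
            stack.append(("V", i, j))
            j = i - 1
        while stack:
            kind, i, j = stack.pop()
            if kind == "V":
                pairs.add((i + 1, j + 1))  # 1-based
                c = int(Vc[i, j])
                if c == 1:
                    stack.append(("V", i + 1, j - 1))
                elif c == 2:
                    stack.append(("V", i + 2, j - 1))
                elif c == 3:
                    stack.append(("V", i + 1, j - 2))
                elif c == 4:
                    stack.append(("V", i + 2, j - 2))
                elif c == 5:
                    k = int(Vk[i, j])
                    stack.append(("M", i + 1, k))
                    stack.append(("M", k + 1, j - 1))
            else:
                c = int(WMc[i, j])
                if c == 0:
                    stack.append(("V", i, j))
                elif c == 1:
                    stack.append(("M", i + 1, j))
                elif c == 2:
                    stack.append(("M", i, j - 1))
                else:
                    k = int(WMk[i, j])
                    stack.append(("M", i, k))
                    stack.append(("M", k + 1, j))
        if not allow_lonely_pairs:
            pairs = _remove_lonely_pairs(pairs)
        return pairs


class ViennaRNAEngine:
    """Adapter to the ViennaRNA nearest-neighbor MFE folder.

    Per-base restraint energies are applied as soft constraints on every
    admissible pair (the energy of pair i/j gains penalties[i] +
    penalties[j], Vienna's native per-pair convention).  Requires the
    ``RNA`` python bindings.
    """

    name = "viennarna"

    def fold(self, sequence: str, penalties: np.ndarray,
             max_pair_distance: int = 600,
             allow_lonely_pairs: bool = False) -> set[tuple[int, int]]:
        try:
            import RNA
        except ImportError as exc:  # pragma: no cover
            raise FoldingError("ViennaRNA python bindings are not installed") from exc
        n = len(sequence)
        pen = np.nan_to_num(np.asarray(penalties, dtype=float), nan=0.0)
        md = RNA.md()
        md.max_bp_span = int(max_pair_distance)
        md.noLP = 0 if allow_lonely_pairs else 1
        fc = RNA.fold_compound(sequence, md)
        if np.any(pen != 0):
            for i in range(1, n + 1):
                for j in range(i + 4, min(n, i + max_pair_distance) + 1):
                    e = pen[i - 1] + pen[j - 1]
                    if e != 0.0:
                        fc.sc_add_bp(i, j, float(e))
        db, _ = fc.mfe()
        from .formats import decode_dotbracket

        pt = decode_dotbracket(db)
        return {(i, int(pt[i])) for i in range(1, n + 1) if pt[i] > i}


def fold(sequence: str, pseudo_energies=None, engine=None,
         max_pair_distance: int = 600,
         allow_lonely_pairs: bool = False,
         structure_id: str = "prediction") -> ReferenceStructure:
    """Predict one pseudoknot-free structure under optional restraints.

    ``pseudo_energies`` is a per-base energy vector (NaN = no restraint);
    with all-zero energies the output is the engine's unconstrained
    prediction.  Engine failures surface with the engine name and a
    digest of the input.
    """
    engine = engine if engine is not None else BuiltinEngine()
    if pseudo_energies is None:
        pseudo_energies = np.zeros(len(sequence))
    try:
        pairs = engine.fold(sequence, pseudo_energies,
                            max_pair_distance=max_pair_distance,
                            allow_lonely_pairs=allow_lonely_pairs)
    except Exception as exc:
        digest = hashlib.sha1(sequence.encode()).hexdigest()[:12]
        raise FoldingError(
            f"engine '{getattr(engine, 'name', engine)}' failed on input "
            f"{digest} (n={len(sequence)}): {exc}") from exc
    for i, j in pairs:
        if j - i > max_pair_distance:
            raise FoldingError(
                f"engine '{engine.name}' returned pair ({i},{j}) beyond the "
                f"maximum pairing distance {max_pair_distance}")
    return ReferenceStructure.from_pairs(structure_id, sequence, pairs)


# ---------------------------------------------------------------------------
# Scoring

@dataclass(frozen=True)
class PredictionScore:
    ppv: float
    sensitivity: float

    @property
    def gmean(self) -> float:
        return float(np.sqrt(self.ppv * self.sensitivity))


def _relaxation(pair: tuple[int, int]) -> tuple[tuple[int, int], ...]:
    i, j = pair
    return ((i, j), (i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1))


def relaxed_compare(predicted: ReferenceStructure, reference: ReferenceStructure,
                    relaxed: bool = True) -> PredictionScore:
    """PPV and sensitivity of a predicted structure against a reference.

    Relaxed mode accepts a predicted pair i/j when the reference contains
    i/j, i-1/j, i+1/j, i/j-1 or i/j+1, and symmetrically counts a
    reference pair as recovered when any predicted pair falls within its
    one-nucleotide relaxation.  Strict mode requires exact matches.  A
    prediction with no pairs scores ppv = 0.
    """
    if predicted.n != reference.n:
        raise ValueError(
            f"predicted length {predicted.n} != reference length {reference.n}")
    pred = set(predicted.pairs())
    ref = set(reference.pairs())
    if not ref:
        raise ValueError("reference structure has no pairs")
    if relaxed:
        n_pred_ok = sum(1 for p in pred if any(q in ref for q in _relaxation(p)))
        n_ref_ok = sum(1 for q in ref if any(p in pred for p in _relaxation(q)))
    else:
        n_pred_ok = len(pred & ref)
        n_ref_ok = n_pred_ok
    ppv = n_pred_ok / len(pred) if pred else 0.0
    sens = n_ref_ok / len(ref)
    return PredictionScore(ppv=ppv, sensitivity=sens)


# ---------------------------------------------------------------------------
# Grid search (jackknifing)

@dataclass
class SlopeInterceptGrid:
    m_values: np.ndarray
    b_values: np.ndarray
    scores: np.ndarray  # mean gmean per (m, b) cell; NaN = fold failure
    per_rna: np.ndarray  # (n_m, n_b, n_rna) gmeans

    @property
    def best_index(self) -> tuple[int, int]:
        """Argmax cell; ties resolve toward smaller |m|, then smaller |b|."""
        valid = ~np.isnan(self.scores)
        if not valid.any():
            raise FoldingError("every grid cell failed")
        best = np.nanmax(self.scores)
        cand = [(abs(self.m_values[i]), abs(self.b_values[j]), i, j)
                for i, j in zip(*np.where(self.scores == best))]
        _, _, i, j = min(cand)
        return int(i), int(j)

    @property
    def best_params(self) -> PseudoEnergyParams:
        i, j = self.best_index
        return PseudoEnergyParams(m=float(self.m_values[i]), b=float(self.b_values[j]))

    @property
    def best_score(self) -> float:
        i, j = self.best_index
        return float(self.scores[i, j])


def default_m_grid() -> np.ndarray:
    return np.round(np.arange(0.0, 5.0 + 1e-9, 0.2), 10)


def default_b_grid() -> np.ndarray:
    return np.round(np.arange(-3.0, 0.0 + 1e-9, 0.2), 10)


def grid_search(profiles, m_grid=None, b_grid=None, engine=None,
                max_pair_distance: int = 600, allow_lonely_pairs: bool = False,
                relaxed: bool = True) -> SlopeInterceptGrid:
    """Exhaustive slope/intercept search over a set of (reactivity,
    reference) pairs.

    Each cell folds every RNA with that (m, b), scores it with the relaxed
    comparison, and stores the mean per-RNA gmean.  A fold failure marks
    the cell invalid (NaN) and the search continues.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one (reactivity, reference) pair")
    m_grid = default_m_grid() if m_grid is None else np.asarray(m_grid, float)
    b_grid = default_b_grid() if b_grid is None else np.asarray(b_grid, float)
    if m_grid.size == 0 or b_grid.size == 0:
        raise ValueError("grids must be non-empty")
    engine = engine if engine is not None else BuiltinEngine()
    per_rna = np.full((m_grid.size, b_grid.size, len(profiles)), np.nan)
    for ia, m in enumerate(m_grid):
        for ib, b in enumerate(b_grid):
            params = PseudoEnergyParams(m=float(m), b=float(b))
            try:
                for k, (react, ref_struct) in enumerate(profiles):
                    energies = pseudo_energy(react, params)
                    pred = fold(ref_struct.sequence, energies, engine=engine,
                                max_pair_distance=max_pair_distance,
                                allow_lonely_pairs=allow_lonely_pairs)
                    per_rna[ia, ib, k] = relaxed_compare(pred, ref_struct,
                                                         relaxed=relaxed).gmean
            except FoldingError:
                per_rna[ia, ib, :] = np.nan
    scores = per_rna.mean(axis=2)
    return SlopeInterceptGrid(m_values=m_grid, b_values=b_grid,
                              scores=scores, per_rna=per_rna)
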