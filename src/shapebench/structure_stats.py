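"""Hairpin-loop signal-to-noise statistic and pairing-state classification.

The signal-to-noise statistic scores a probing reagent by contrasting
reactivity at hairpin loops (expected flexible, reactive) with the
adjacent stem bases (expected constrained, unreactive).  Hairpins are
found on the literal dot-bracket string with the regular expression
``([\\(]{3}\\.{3,}[\\)]{3})`` — three stacked opening brackets, a loop of
at least three dots, three closing brackets — so a bulge interrupting the
closing helix disqualifies a hairpin.  A structure-aware variant is
available behind a flag.  Pseudoknot bracket layers are flattened to '.'
before matching, since the pattern recognizes only '(', ')' and '.'.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .formats import ReferenceStructure
from .reactivity import ReactivityProfile

__all__ = [
    "HairpinLoop",
    "HAIRPIN_PATTERN",
    "extract_hairpins",
    "signal_to_noise",
    "loop_position_profile",
    "classify_pairing_state",
    "UNPAIRED",
    "TERMINAL",
    "INTERNAL",
]

HAIRPIN_PATTERN = re.compile(r"([\(]{3}\.{3,}[\)]{3})")


@dataclass(frozen=True)
class HairpinLoop:
    """A hairpin: contiguous 1-based loop positions flanked by the three
    stem positions on each side."""

    loop: tuple[int, ...]
    stem5: tuple[int, int, int]
    stem3: tuple[int, int, int]

    @property
    def loop_edge(self) -> tuple[int, ...]:
        """First two and last two loop bases (distinct positions), the bases
        the signal statistic evaluates."""
        k = len(self.loop)
        idx = sorted({0, 1, k - 2, k - 1})
        return tuple(self.loop[i] for i in idx)

    @property
    def stems(self) -> tuple[int, ...]:
        return self.stem5 + self.stem3


def flatten_pseudoknots(dotbracket: str) -> str:
    """Replace every character outside '(', ')', '.' with '.'."""
    return "".join(c if c in "()." else "." for c in dotbracket)


def extract_hairpins(structure: ReferenceStructure | str,
                     structure_aware: bool = False) -> list[HairpinLoop]:
    """Find hairpin loops with stem length >= 3 and loop size >= 3.

    Default: non-overlapping left-to-right regex matches on the flattened
    dot-bracket string.  ``structure_aware=True`` instead walks the pair
    table, requiring three consecutive stacked closing pairs (tolerant of
    string-level interruptions such as pseudoknot brackets inside the
    helix rendering).
    """
    if isinstance(structure, str):
        db = structure
        if structure_aware:
            raise ValueError("structure-aware extraction needs a ReferenceStructure")
    else:
        db = structure.dotbracket
    if structure_aware:
        return _extract_hairpins_pairtable(structure)
    flat = flatten_pseudoknots(db)
    out = []
    for m in HAIRPIN_PATTERN.finditer(flat):
        a, b = m.start() + 1, m.end()  # 1-based inclusive span
        loop = tuple(range(a + 3, b - 2))
        out.append(HairpinLoop(loop=loop, stem5=(a, a + 1, a + 2),
                               stem3=(b - 2, b - 1, b)))
    return out


def _extract_hairpins_pairtable(structure: ReferenceStructure) -> list[HairpinLoop]:
    pt = structure.pair_table
    n = structure.n
    paired = {(i, int(pt[i])) for i in range(1, n + 1) if pt[i] > i}
    out = []
    for i, j in sorted(paired):
        # (i, j) closes a hairpin loop iff everything strictly inside is unpaired
        if j - i - 1 < 3 or any(pt[k] for k in range(i + 1, j)):
            continue
        if (i - 1, j + 1) in paired and (i - 2, j + 2) in paired:
            loop = tuple(range(i + 1, j))
            out.append(HairpinLoop(loop=loop, stem5=(i - 2, i - 1, i),
                                   stem3=(j, j + 1, j + 2)))
    return out


def _values_at(profile, positions) -> np.ndarray:
    values = profile.values if isinstance(profile, ReactivityProfile) else np.asarray(profile, float)
    return values[[p - 1 for p in positions]]


def signal_to_noise(hairpins: list[HairpinLoop], profile, pooled: bool = False,
                    return_details: bool = False):
    """Loop/stem reactivity ratio across hairpins.

    Per hairpin, the loop statistic is the median reactivity over the
    first and last two loop bases and the stem statistic the median over
    the three bases before and after the loop.  The default returns
    (median of per-hairpin loop statistics) / (median of per-hairpin stem
    statistics); ``pooled=True`` instead pools all evaluated bases before
    taking the two medians.  Hairpins with any undefined evaluated base
    are skipped and reported in the details.
    """
    loop_stats, stem_stats, skipped = [], [], 0
    loop_pool, stem_pool = [], []
    for hp in hairpins:
        lv = _values_at(profile, hp.loop_edge)
        sv = _values_at(profile, hp.stems)
        if np.isnan(lv).any() or np.isnan(sv).any():
            skipped += 1
            continue
        loop_stats.append(float(np.median(lv)))
        stem_stats.append(float(np.median(sv)))
        loop_pool.extend(lv)
        stem_pool.extend(sv)
    if not loop_stats:
        raise ValueError("no hairpin with fully defined reactivities")
    if pooled:
        num, den = float(np.median(loop_pool)), float(np.median(stem_pool))
    else:
        num, den = float(np.median(loop_stats)), float(np.median(stem_stats))
    if den == 0:
        raise ValueError("stem median reactivity is zero: degenerate profile")
    snr = num / den
    if return_details:
        return snr, {"per_loop": loop_stats, "per_stem": stem_stats,
                     "n_hairpins": len(loop_stats), "n_skipped": skipped,
                     "pooled": float(np.median(loop_pool)) / float(np.median(stem_pool))
                     if np.median(stem_pool) else np.nan}
    return snr


# Relative positions reported by the loop-position profile: -3..-1 are the
# stem bases 5' of the loop, 0 and +1 the first two loop bases; primed
# labels mirror from the 3' side (0' = last loop base, -1'..-3' = 3' stem).
LOOP_PROFILE_KEYS = ("-3", "-2", "-1", "0", "+1", "+1'", "0'", "-1'", "-2'", "-3'")


def loop_position_profile(hairpins: list[HairpinLoop], profile) -> dict[str, float]:
    """Median reactivity across hairpins at each loop-relative position."""
    collected: dict[str, list[float]] = {k: [] for k in LOOP_PROFILE_KEYS}
    for hp in hairpins:
        loop = hp.loop
        pos_map = {
            "-3": hp.stem5[0], "-2": hp.stem5[1], "-1": hp.stem5[2],
            "0": loop[0], "+1": loop[1],
            "+1'": loop[-2], "0'": loop[-1],
            "-1'": hp.stem3[0], "-2'": hp.stem3[1], "-3'": hp.stem3[2],
        }
        for key, p in pos_map.items():
            v = float(_values_at(profile, [p])[0])
            if not np.isnan(v):
                collected[key].append(v)
    return {k: (float(np.median(v)) if v else float("nan"))
            for k, v in collected.items()}


# Pairing states
UNPAIRED, TERMINAL, INTERNAL = 0, 1, 2
PAIRING_STATE_NAMES = {UNPAIRED: "unpaired", TERMINAL: "terminally-paired",
                       INTERNAL: "internally-paired"}


def classify_pairing_state(structure: ReferenceStructure) -> np.ndarray:
    """Label each base unpaired / terminally-paired / internally-paired.

    A paired base i with partner j is internally paired iff both (i-1, j+1)
    and (i+1, j-1) are pairs of the structure; otherwise it sits at a helix
    end (isolated pairs included) and is terminally paired.  Returns a
    length-(n+1) int array indexed 1-based; entry 0 is unused.
    """
    pt = structure.pair_table
    n = structure.n
    labels = np.zeros(n + 1, dtype=np.int8)

    def is_pair(a: int, b: int) -> bool:
        return 1 <= a <= n and 1 <= b <= n and int(pt[a]) == b

    for i in range(1, n + 1):
        j = int(pt[i])
        if j == 0:
            labels[i] = UNPAIRED
        elif is_pair(i - 1, j + 1) and is_pair(i + 1, j - 1):
            labels[i] = INTERNAL
        else:
            labels[i] = TERMINAL
    return labels
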