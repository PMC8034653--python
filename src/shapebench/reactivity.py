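"""Reactivity profiles: control subtraction and box-plot normalization.

A reactivity profile holds one non-negative value per base, with NaN
marking missing data; missing stays missing through every transform.
ROC and signal-to-noise statistics default to raw treated-channel
frequencies elsewhere in the package; control-subtracted, normalized
profiles are the default input to restrained folding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .counting import MutationProfile

__all__ = ["ReactivityProfile", "subtract_control", "normalize_boxplot"]


@dataclass
class ReactivityProfile:
    transcript_id: str
    values: np.ndarray  # non-negative, NaN = missing
    provenance: tuple[str, ...] = ("raw",)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        defined = self.values[~np.isnan(self.values)]
        if defined.size and defined.min() < 0:
            raise ValueError("reactivities must be non-negative")

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def defined(self) -> np.ndarray:
        return ~np.isnan(self.values)

    @classmethod
    def from_frequencies(cls, profile: MutationProfile) -> "ReactivityProfile":
        return cls(transcript_id=profile.transcript_id,
                   values=profile.frequency, provenance=("raw",))


def subtract_control(treated: MutationProfile, control: MutationProfile) -> ReactivityProfile:
    """Background-subtracted reactivity: max(0, f_treated - f_control).

    Positions with an undefined frequency in either channel are missing in
    the result.  Pointwise monotone in the treated frequency and antitone
    in the control frequency.
    """
    if treated.n != control.n:
        raise ValueError(
            f"treated ({treated.n}) and control ({control.n}) profile lengths differ")
    ft, fc = treated.frequency, control.frequency
    values = np.clip(ft - fc, 0.0, None)
    values[np.isnan(ft) | np.isnan(fc)] = np.nan
    return ReactivityProfile(transcript_id=treated.transcript_id, values=values,
                             provenance=("control-subtracted",))


def normalize_boxplot(profile: ReactivityProfile) -> ReactivityProfile:
    """Box-plot normalization, the community default for SHAPE restraints.

    Values above Q3 + 1.5*IQR of the defined values are set aside as
    outliers; the mean of the top 10% of the remaining values is the
    normalizer; every value (outliers included) is divided by it.
    Requires >= 10 defined values and a nonzero normalizer.
    """
    values = profile.values
    defined = values[~np.isnan(values)]
    if defined.size == 0:
        raise ValueError("cannot normalize an all-missing profile")
    if defined.size < 10:
        raise ValueError(f"need >= 10 defined values to normalize, got {defined.size}")
    q1, q3 = np.percentile(defined, [25, 75])
    cutoff = q3 + 1.5 * (q3 - q1)
    inliers = np.sort(defined[defined <= cutoff])
    n_top = max(1, int(np.ceil(0.1 * inliers.size)))
    norm = float(inliers[-n_top:].mean())
    if norm <= 0:
        raise ValueError("normalizer is zero (profile has no signal)")
    return ReactivityProfile(transcript_id=profile.transcript_id,
                             values=values / norm,
                             provenance=profile.provenance + ("normalized",))
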