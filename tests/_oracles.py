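"""Independent reference implementations used only by the test suite.

These deliberately use different mechanics from the package (per-column
pileup with string-level deletion enumeration, random rejection sampling
for SASA, the standard library's regex engine directly) so agreement is
a real cross-check, not a tautology.
"""

from __future__ import annotations

import re

import numpy as np


def pileup_oracle(reads, ref, qmin=20, realign=True, count_ins=True):
    """Brute-force per-column pileup with enumeration-based deletion
    re-alignment (all equivalent placements tried, rightmost kept)."""
    ref = ref.upper().replace("T", "U")
    n = len(ref)
    counts = np.zeros(n, dtype=int)
    cover = np.zeros(n, dtype=int)
    for read in reads:
        if not (read.is_mapped and read.is_primary):
            continue
        start = read.pos - 1
        span = sum(ln for op, ln in read.cigar if op in "MDN=X")
        if start < 0 or start + span > n:
            continue
        # expand the alignment into columns
        cols = []
        rp, si = start, 0
        for op, ln in read.cigar:
            if op in "M=X":
                for _ in range(ln):
                    cols.append(("M", rp, read.seq[si], int(read.qual[si])))
                    rp += 1
                    si += 1
            elif op == "I":
                cols.append(("I", rp, read.seq[si:si + ln],
                             [int(q) for q in read.qual[si:si + ln]]))
                si += ln
            elif op == "D":
                cols.append(("D", rp, ln, None))
                rp += ln
            elif op == "N":
                rp += ln
            elif op == "S":
                si += ln
        if realign:
            cols = _realign_columns(cols, ref)
        # score
        events, covered = set(), set()
        pending = None
        for col in cols:
            kind = col[0]
            if kind == "M":
                _, pos, base, q = col
                if q >= qmin:
                    covered.add(pos)
                    ev = base != ref[pos] and base != "N" and ref[pos] != "N"
                    if pending == pos:
                        ev = True
                    if ev:
                        events.add(pos)
                if pending == pos:
                    pending = None
            elif kind == "I":
                if count_ins and min(col[3]) >= qmin:
                    pending = col[1]
            elif kind == "D":
                _, pos, dl, _ = col
                dq = _deletion_flank_qual(cols, col)
                for t in range(dl):
                    if dq >= qmin:
                        covered.add(pos + t)
                        events.add(pos + t)
                    if pending == pos + t:
                        pending = None
        for pos in covered:
            cover[pos] += 1
        for pos in events:
            counts[pos] += 1
    return counts, cover


def _deletion_flank_qual(cols, dcol):
    """Min quality of the read bases flanking a deletion run (255 if a
    side has no read base)."""
    idx = cols.index(dcol)
    left = right = 255
    for c in reversed(cols[:idx]):
        if c[0] == "M":
            left = c[3]
            break
        if c[0] == "I":
            left = c[3][-1]
            break
    for c in cols[idx + 1:]:
        if c[0] == "M":
            right = c[3]
            break
        if c[0] == "I":
            right = c[3][0]
            break
    return min(left, right)


def _realign_columns(cols, ref):
    """Move each deletion run to its rightmost equivalent placement by
    enumerating every placement that leaves the same remaining reference
    string over the deletion-plus-following-match window."""
    out = []
    idx = 0
    while idx < len(cols):
        col = cols[idx]
        if col[0] != "D":
            out.append(col)
            idx += 1
            continue
        p, dl = col[1], col[2]
        follow = []
        k = idx + 1
        while k < len(cols) and cols[k][0] == "M":
            follow.append(cols[k])
            k += 1
        window_end = p + dl + len(follow)
        reference_removed = ref[p:p] + ref[p + dl:window_end]
        best = p
        for pp in range(p, p + len(follow) + 1):
            if ref[p:pp] + ref[pp + dl:window_end] == reference_removed:
                best = pp
        shift = best - p
        for t in range(shift):
            out.append(("M", p + t, follow[t][2], follow[t][3]))
        out.append(("D", best, dl, None))
        for t in range(shift, len(follow)):
            out.append(("M", best + dl + (t - shift), follow[t][2], follow[t][3]))
        idx = k
    return out


def regex_hairpin_oracle(dotbracket: str):
    """Standalone evaluation of the hairpin pattern: three stacked '(',
    >= 3 dots, three ')' on the pseudoknot-flattened string.  Returns
    (stem5, loop, stem3) position tuples, 1-based."""
    flat = "".join(c if c in "()." else "." for c in dotbracket)
    out = []
    for m in re.finditer(r"\(\(\(\.{3,}\)\)\)", flat):
        s, e = m.start() + 1, m.end()  # 1-based inclusive span
        out.append((tuple(range(s, s + 3)),
                    tuple(range(s + 3, e - 2)),
                    tuple(range(e - 2, e + 1))))
    return out


def sasa_mc_oracle(residues, probe_radius, n_samples=4000, seed=0):
    """Monte-Carlo SASA: random directions per atom instead of the
    deterministic lattice."""
    rng = np.random.default_rng(seed)
    coords = np.concatenate([r.coords() for r in residues])
    radii = np.concatenate([r.radii() for r in residues])
    owner = np.concatenate([np.full(len(r.atoms), k) for k, r in enumerate(residues)])
    expanded = radii + probe_radius
    per_res = np.zeros(len(residues))
    for i in range(len(coords)):
        d = rng.normal(size=(n_samples, 3))
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        pts = coords[i] + expanded[i] * d
        free = np.ones(n_samples, dtype=bool)
        for j in range(len(coords)):
            if j == i:
                continue
            free &= np.sum((pts - coords[j]) ** 2, axis=1) >= expanded[j] ** 2
        per_res[owner[i]] += 4.0 * np.pi * expanded[i] ** 2 * free.mean()
    return per_res


def mann_whitney_auc(values, labels):
    """Exact rank-statistic AUC with tie correction (the probabilistic
    interpretation of the ROC area)."""
    from sklearn.metrics import roc_auc_score

    return float(roc_auc_score(labels, values))
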