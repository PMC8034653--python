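"""Numba kernels for the hot paths: pileup counting, simulated-read
assembly, and the built-in folding engine's dynamic program.

All kernels are deterministic; randomness stays in the callers.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# CIGAR op codes used in packed read batches
OP_M, OP_I, OP_D, OP_N, OP_S, OP_H, OP_P = 0, 1, 2, 3, 4, 5, 6

_ASCII_N = 78  # 'N'


@njit(cache=True)
def count_kernel(ref, starts, cig_ops, cig_lens, cig_off, seqs, seq_off, quals,
                 qmin, realign_deletions, count_insertions, counts, coverage):
    """Accumulate mutation events and coverage from packed alignments.

    Semantics: a position is covered when an aligned base (or deletion)
    spans it with quality >= qmin (deletions inherit the min flanking read
    base quality).  Events are mismatches, deletions (each deleted
    reference position once) and insertions (charged to the reference
    position immediately 3' of the insertion, if that position is covered
    by the same read).  At most one event per read per position, so
    counts <= coverage holds everywhere.  Ambiguous deletions are shifted
    to their rightmost equivalent placement when realign_deletions is set.
    Returns the number of skipped reads (alignment exceeding the
    reference).
    """
    n = ref.shape[0]
    n_reads = starts.shape[0]
    skipped = 0
    for r in range(n_reads):
        o0, o1 = cig_off[r], cig_off[r + 1]
        s0 = seq_off[r]
        # reference span check
        span = 0
        for c in range(o0, o1):
            if cig_ops[c] == OP_M or cig_ops[c] == OP_D or cig_ops[c] == OP_N:
                span += cig_lens[c]
        rp = starts[r]
        if rp < 0 or rp + span > n:
            skipped += 1
            continue
        n_ops = o1 - o0
        lens = np.empty(n_ops, np.int64)
        for c in range(n_ops):
            lens[c] = cig_lens[o0 + c]
        si = s0
        seq_end = seq_off[r + 1]
        pending_ins = np.int64(-1)
        for c in range(n_ops):
            op = cig_ops[o0 + c]
            ln = lens[c]
            if op == OP_M:
                for _ in range(ln):
                    q = quals[si]
                    if q >= qmin:
                        coverage[rp] += 1
                        b = seqs[si]
                        ev = (b != ref[rp]) and b != _ASCII_N and ref[rp] != _ASCII_N
                        if pending_ins == rp:
                            ev = True
                        if ev:
                            counts[rp] += 1
                    if pending_ins == rp:
                        pending_ins = -1
                    rp += 1
                    si += 1
            elif op == OP_I:
                if count_insertions:
                    q = np.uint8(255)
                    for t in range(ln):
                        if quals[si + t] < q:
                            q = quals[si + t]
                    if q >= qmin:
                        pending_ins = rp
                si += ln
            elif op == OP_D:
                dl = ln
                if realign_deletions and c + 1 < n_ops and cig_ops[o0 + c + 1] == OP_M:
                    ml = lens[c + 1]
                    k = np.int64(0)
                    while k < ml and rp + dl + k < n and ref[rp + k] == ref[rp + dl + k]:
                        k += 1
                    if k > 0:
                        # the first k bases of the following match segment
                        # slide left of the deletion; mismatch status is
                        # unchanged because ref[rp+t] == ref[rp+dl+t]
                        for _ in range(k):
                            q = quals[si]
                            if q >= qmin:
                                coverage[rp] += 1
                                b = seqs[si]
                                ev = (b != ref[rp]) and b != _ASCII_N and ref[rp] != _ASCII_N
                                if pending_ins == rp:
                                    ev = True
                                if ev:
                                    counts[rp] += 1
                            if pending_ins == rp:
                                pending_ins = -1
                            rp += 1
                            si += 1
                        lens[c + 1] = ml - k
                # flanking base qualities (post-realignment)
                ql = quals[si - 1] if si > s0 else np.uint8(255)
                qr = quals[si] if si < seq_end else np.uint8(255)
                dq = ql if ql < qr else qr
                for _ in range(dl):
                    if dq >= qmin:
                        coverage[rp] += 1
                        counts[rp] += 1
                    if pending_ins == rp:
                        pending_ins = -1
                    rp += 1
            elif op == OP_N:
                rp += ln
            elif op == OP_S:
                si += ln
            # H and P consume nothing we track
    return skipped


@njit(cache=True)
def assemble_reads_kernel(ref, starts, mut, base_code, code_base):
    """Build packed alignments from a per-read mutation plan.

    ``mut[r, t]`` describes position t of read r's reference window:
    0 = match, 1..3 = mismatch (cyclic base offset), 4 = single-base
    deletion.  Leading/trailing deletions are trimmed from the alignment
    (the start shifts right) so CIGARs begin and end with a match run.
    Returns packed arrays: adjusted 0-based starts, flattened sequences
    with offsets, and merged CIGAR runs with offsets.
    """
    nr, L = mut.shape
    out_starts = np.empty(nr, np.int64)
    seq_off = np.zeros(nr + 1, np.int64)
    cig_off = np.zeros(nr + 1, np.int64)

    # pass 1: window trimming and op-run counting
    a_arr = np.empty(nr, np.int64)
    b_arr = np.empty(nr, np.int64)
    for r in range(nr):
        a = 0
        while a < L and mut[r, a] == 4:
            a += 1
        b = L
        while b > a and mut[r, b - 1] == 4:
            b -= 1
        if b <= a:  # fully deleted window: degenerate single-base match
            a, b = 0, 1
            mut[r, 0] = 0
        a_arr[r] = a
        b_arr[r] = b
        n_ops = 1
        nbases = 0
        prev_del = False
        for t in range(a, b):
            is_del = mut[r, t] == 4
            if t > a and is_del != prev_del:
                n_ops += 1
            if not is_del:
                nbases += 1
            prev_del = is_del
        seq_off[r + 1] = seq_off[r] + nbases
        cig_off[r + 1] = cig_off[r] + n_ops

    seqs = np.empty(seq_off[nr], np.uint8)
    cig_ops = np.empty(cig_off[nr], np.int8)
    cig_lens = np.empty(cig_off[nr], np.int32)

    # pass 2: fill
    for r in range(nr):
        a, b = a_arr[r], b_arr[r]
        out_starts[r] = starts[r] + a
        si = seq_off[r]
        ci = cig_off[r]
        run_len = 0
        run_del = mut[r, a] == 4
        for t in range(a, b):
            is_del = mut[r, t] == 4
            if is_del != run_del:
                cig_ops[ci] = OP_D if run_del else OP_M
                cig_lens[ci] = run_len
                ci += 1
                run_len = 0
                run_del = is_del
            run_len += 1
            if not is_del:
                rb = ref[starts[r] + t]
                m = mut[r, t]
                if m == 0:
                    seqs[si] = rb
                else:
                    code = base_code[rb]
                    if code < 4:
                        seqs[si] = code_base[(code + m) % 4]
                    else:
                        seqs[si] = rb
                si += 1
        cig_ops[ci] = OP_D if run_del else OP_M
        cig_lens[ci] = run_len
    return out_starts, seqs, seq_off, cig_ops, cig_lens, cig_off


# ---------------------------------------------------------------------------
# Folding dynamic program

_INF = 1.0e18


@njit(cache=True)
def fold_fill(codes, pen, max_dist, pair_e, e_stack, e_hairpin, e_bulge,
              e_int11, e_multi):
    """Minimum-energy fill for the built-in nested-structure engine.

    V[i,j]: best energy with (i,j) paired; interior closed by a hairpin,
    a stacked pair, a single-base bulge, a 1x1 internal loop, or a
    multiloop decomposed through WM (which contains >= 1 helix per part).
    Per-nucleotide pseudo-energies ``pen`` are charged to both partners of
    every formed pair.  Ties always resolve to the first option in a fixed
    order, so the traceback is deterministic.
    """
    n = codes.shape[0]
    V = np.full((n, n), _INF)
    WM = np.full((n, n), _INF)
    Vc = np.zeros((n, n), np.int8)
    Vk = np.full((n, n), -1, np.int32)
    WMc = np.zeros((n, n), np.int8)
    WMk = np.full((n, n), -1, np.int32)

    for s in range(4, n):
        for i in range(0, n - s):
            j = i + s
            ci, cj = codes[i], codes[j]
            pe = pair_e[ci, cj] if (ci >= 0 and cj >= 0) else _INF
            if s <= max_dist and pe < _INF / 2:
                best = e_hairpin
                bc = np.int8(0)
                bk = np.int32(-1)
                v = V[i + 1, j - 1]
                if v < _INF / 2 and v + e_stack < best:
                    best = v + e_stack
                    bc = 1
                if i + 2 < j - 1:
                    v = V[i + 2, j - 1]
                    if v < _INF / 2 and v + e_bulge < best:
                        best = v + e_bulge
                        bc = 2
                if i + 1 < j - 2:
                    v = V[i + 1, j - 2]
                    if v < _INF / 2 and v + e_bulge < best:
                        best = v + e_bulge
                        bc = 3
                if i + 2 < j - 2:
                    v = V[i + 2, j - 2]
                    if v < _INF / 2 and v + e_int11 < best:
                        best = v + e_int11
                        bc = 4
                for k in range(i + 1, j - 1):
                    w1 = WM[i + 1, k]
                    if w1 >= _INF / 2:
                        continue
                    w2 = WM[k + 1, j - 1]
                    if w2 >= _INF / 2:
                        continue
                    cand = e_multi + w1 + w2
                    if cand < best:
                        best = cand
                        bc = 5
                        bk = k
                V[i, j] = pe + pen[i] + pen[j] + best
                Vc[i, j] = bc
                Vk[i, j] = bk
            # WM: at least one helix somewhere in [i, j]
            best = V[i, j]
            bc = np.int8(0)
            bk = np.int32(-1)
            if WM[i + 1, j] < best:
                best = WM[i + 1, j]
                bc = 1
            if WM[i, j - 1] < best:
                best = WM[i, j - 1]
                bc = 2
            for k in range(i + 4, j - 4):
                w1 = WM[i, k]
                if w1 >= _INF / 2:
                    continue
                w2 = WM[k + 1, j]
                if w2 >= _INF / 2:
                    continue
                if w1 + w2 < best:
                    best = w1 + w2
                    bc = 3
                    bk = k
            if best < _INF / 2:
                WM[i, j] = best
                WMc[i, j] = bc
                WMk[i, j] = bk

    # external strand: W[t] = best energy of prefix 0..t-1
    W = np.zeros(n + 1)
    ptr = np.full(n, -1, np.int32)
    for j in range(n):
        best = W[j]
        bi = np.int32(-1)
        for i in range(0, j):
            if V[i, j] < _INF / 2:
                cand = W[i] + V[i, j]
                if cand < best:
                    best = cand
                    bi = i
        W[j + 1] = best
        ptr[j] = bi
    return V, Vc, Vk, WMc, WMk, ptr
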