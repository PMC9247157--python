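"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the production code paths: no purine-tract seeding,
no diagonal prescreens — every strand, motif, alignment offset and window is
checked directly from the definitions.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

RNA_PARTNERS = {
    "pyrimidine_parallel": {("U", "A"), ("C", "G")},
    "purine_antiparallel": {("A", "A"), ("G", "G")},
    "GT_parallel": {("G", "G"), ("U", "A")},
    "GT_antiparallel": {("G", "G"), ("U", "A")},
}
ANTIPARALLEL = {"purine_antiparallel", "GT_antiparallel"}
MOTIF_PRIORITY = ["pyrimidine_parallel", "purine_antiparallel",
                  "GT_parallel", "GT_antiparallel"]

_COMP = str.maketrans("ACGT", "TGCA")


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def oracle_tts(window: str, min_len: int = 15, max_err: float = 0.20):
    """All maximal purine tracts on both strands, by direct enumeration."""
    q = 1 - Fraction(str(max_err))
    out = set()
    n = len(window)
    for strand, seq in (("+", window), ("-", None)):
        is_good = [b in "AG" if strand == "+" else b in "CT" for b in window]
        cum = np.concatenate([[0], np.cumsum(is_good)])

        def frac_ok(i, j):
            return (cum[j] - cum[i]) * q.denominator >= q.numerator * (j - i)

        for i in range(n):
            for j in range(i + min_len, n + 1):
                if not frac_ok(i, j):
                    continue
                if i > 0 and frac_ok(i - 1, j):
                    continue
                if j < n and frac_ok(i, j + 1):
                    continue
                out.add((i, j, strand))
    return out


def oracle_hits(rna: str, window: str, min_len: int = 15,
                max_err: float = 0.20, min_g: float = 0.10,
                motifs=tuple(MOTIF_PRIORITY)):
    """Exhaustive all-offsets/all-windows triplex hit enumeration.

    Returns {(rna_start0, rna_end0, dna_start, dna_end, strand, mism): motif}
    with 0-based half-open coordinates, keeping the first motif in priority
    order for windows identical under several motifs.
    """
    rna = rna.upper().replace("T", "U")
    q = 1 - Fraction(str(max_err))
    g = Fraction(str(min_g))
    found = {}
    W = len(window)
    for strand in ("+", "-"):
        purine = window if strand == "+" else rc(window)
        for motif in MOTIF_PRIORITY:
            if motif not in motifs:
                continue
            table = RNA_PARTNERS[motif]
            anti = motif in ANTIPARALLEL
            X = rna[::-1] if anti else rna
            R = len(X)
            # match[i][j]: X position i against purine-strand position j
            xa_ = np.array(list(X))
            pa_ = np.array(list(purine))
            m = np.zeros((R, W), dtype=bool)
            for r, d in table:
                m |= (xa_[:, None] == r) & (pa_[None, :] == d)
            valid = np.isin(xa_, list("ACGU"))[:, None] & np.ones(W, bool)[None, :]
            num, den = q.numerator, q.denominator
            for k in range(-W + 1, R):
                i0 = max(0, k)
                j0 = i0 - k
                L = min(R - i0, W - j0)
                if L < min_len:
                    continue
                ii = np.arange(L)
                diag_m = m[i0 + ii, j0 + ii]
                diag_v = valid[i0 + ii, j0 + ii]
                cm = np.concatenate([[0], np.cumsum(diag_m)])
                cv = np.concatenate([[0], np.cumsum(diag_v)])
                # a diagonal begins/ends at a matrix boundary, so there is
                # no extension past t=0 or t=L; within the diagonal an
                # extension exists wherever the neighbouring base is valid
                s_arr = np.arange(0, L - min_len + 1)
                e_arr = np.arange(min_len, L + 1)
                ln = e_arr[None, :] - s_arr[:, None]
                oklen = ln >= min_len
                match_n = cm[e_arr][None, :] - cm[s_arr][:, None]
                all_valid = (cv[e_arr][None, :] - cv[s_arr][:, None]) == ln
                rate_ok = match_n * den >= num * ln
                lm = np.concatenate([[False], diag_m[:-1]])[s_arr]
                lv = np.concatenate([[False], diag_v[:-1]])[s_arr]
                rm = np.concatenate([diag_m[min_len:], [False]])
                rv = np.concatenate([diag_v[min_len:], [False]])
                ext_left = (lv[:, None]
                            & ((match_n + lm[:, None]) * den >= num * (ln + 1)))
                ext_right = (rv[None, :]
                             & ((match_n + rm[None, :]) * den >= num * (ln + 1)))
                keep = oklen & all_valid & rate_ok & ~ext_left & ~ext_right
                for si, ei in zip(*np.nonzero(keep)):
                    s, e = int(s_arr[si]), int(e_arr[ei])
                    xa, xb = i0 + s, i0 + e
                    ja, jb = j0 + s, j0 + e
                    if anti:
                        rs, re = R - xb, R - xa
                    else:
                        rs, re = xa, xb
                    if strand == "+":
                        ws, we = ja, jb
                    else:
                        ws, we = W - jb, W - ja
                    tfo = rna[rs:re]
                    if (tfo.count("G") * g.denominator
                            < g.numerator * len(tfo)):
                        continue
                    key = (rs, re, ws, we, strand,
                           int((e - s) - (cm[e] - cm[s])))
                    if key not in found:
                        found[key] = motif
    return found


def oracle_jt(groups):
    """Jonckheere-Terpstra statistic by direct pair counting (ties as 1/2)."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    if x < y:
                        jt += 1.0
                    elif x == y:
                        jt += 0.5
    return jt


def oracle_hypergeom_p(a, b, c, d):
    """One-sided (greater) exact p for the 2x2 table by enumeration."""
    from math import comb

    n = a + b + c + d
    k_col = a + c
    n_q = a + b
    denom = comb(n, k_col)
    p = 0.0
    for x in range(a, min(n_q, k_col) + 1):
        if k_col - x <= c + d:
            p += comb(n_q, x) * comb(c + d, k_col - x) / denom
    return p


def oracle_merge_coverage(intervals):
    """Covered base set of a list of (chrom, start, end) by per-base marking."""
    cov = set()
    for chrom, s, e in intervals:
        for p in range(s, e):
            cov.add((chrom, p))
    return cov


def oracle_overlap_count(query, subject, min_bp=1):
    """O(n*m) all-pairs overlap counting."""
    n = 0
    for qc, qs, qe in query:
        for sc, ss, se in subject:
            if qc == sc and min(qe, se) - max(qs, ss) >= min_bp:
                n += 1
                break
    return n
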