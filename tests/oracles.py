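"""Independent oracles used by the test suite.

Each function here recomputes an expected result by brute force —
enumeration, exact rational arithmetic, or direct numerical maximization —
without calling into the code paths it is used to check.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb
from typing import List, Optional, Tuple

import numpy as np

_GAMMA = 1 + Fraction(1, 10**7)  # R/scipy two-sided tie convention


# ---------------------------------------------------------------------------
# coverage codec
# ---------------------------------------------------------------------------

def naive_bins(depths) -> str:
    """Per-site binning with no compression (if/elif chain, no bisect)."""
    out = []
    for d in depths:
        if d < 10:
            out.append("a")
        elif d < 20:
            out.append("b")
        elif d < 30:
            out.append("c")
        elif d < 50:
            out.append("d")
        elif d < 200:
            out.append("e")
        else:
            out.append("f")
    return "".join(out)


def naive_rle(letters: str) -> str:
    """Second, index-based RLE encoder."""
    tokens = []
    i = 0
    while i < len(letters):
        j = i
        while j < len(letters) and letters[j] == letters[i]:
            j += 1
        tokens.append(f"{j - i}{letters[i]}")
        i = j
    return "".join(tokens)


# ---------------------------------------------------------------------------
# variant normalization: haplotype-edit enumeration
# ---------------------------------------------------------------------------

def apply_edit(window: str, offset: int, ref: str, alt: str) -> str:
    """Haplotype produced by substituting ref->alt at 0-based window offset."""
    assert window[offset : offset + len(ref)] == ref
    return window[:offset] + alt + window[offset + len(ref) :]


def minimal_representation(
    window: str, window_start: int, haplotype: str
) -> Tuple[int, str, str]:
    """Enumerate every (pos, ref, alt) whose edit to the window yields the
    haplotype; return the minimal-total-allele-length one, ties broken by
    smallest position.  Alleles must be non-empty (VCF convention).
    """
    L = len(window)
    best = None
    for p in range(L):
        for rl in range(1, L - p + 1):
            tail = L - p - rl
            alt_end = len(haplotype) - tail
            if alt_end <= p:
                continue
            alt_c = haplotype[p:alt_end]
            ref_c = window[p : p + rl]
            if ref_c == alt_c:
                continue
            if window[:p] + alt_c + window[p + rl :] != haplotype:
                continue
            key = (rl + len(alt_c), p)
            if best is None or key < best[0]:
                best = (key, p, ref_c, alt_c)
    assert best is not None, "no representation found (haplotype == window?)"
    return window_start + best[1], best[2], best[3]


# ---------------------------------------------------------------------------
# exact test oracles (rational arithmetic)
# ---------------------------------------------------------------------------

def fisher_two_sided(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p for [[a, b], [c, d]] by full hypergeometric
    enumeration with exact fractions."""
    N = a + b + c + d
    row1 = a + b
    col1 = a + c
    denom = comb(N, col1)
    lo = max(0, col1 - (N - row1))
    hi = min(col1, row1)
    pmf = {
        k: Fraction(comb(row1, k) * comb(N - row1, col1 - k), denom)
        for k in range(lo, hi + 1)
    }
    cutoff = pmf[a] * _GAMMA
    p = sum(v for v in pmf.values() if v <= cutoff)
    return float(min(p, Fraction(1)))


def binomial_two_sided(k: int, n: int, p_num: int, p_den: int) -> float:
    """Two-sided exact binomial p (success prob p_num/p_den) by tail summation."""
    p = Fraction(p_num, p_den)
    pmf = {
        i: comb(n, i) * p**i * (1 - p) ** (n - i) for i in range(n + 1)
    }
    cutoff = pmf[k] * _GAMMA
    total = sum(v for v in pmf.values() if v <= cutoff)
    return float(min(total, Fraction(1)))


# ---------------------------------------------------------------------------
# Firth logistic: direct maximization of the penalized likelihood
# ---------------------------------------------------------------------------

def firth_direct_maximization(x, y) -> Tuple[float, float]:
    """Maximize the Jeffreys-penalized log-likelihood of a two-parameter
    logistic model (intercept + slope) with a derivative-free optimizer.
    Returns (intercept, slope)."""
    from scipy.optimize import minimize

    x = np.asarray(x, float)
    y = np.asarray(y, float)
    X = np.column_stack([np.ones_like(x), x])

    def neg_pen_ll(beta):
        eta = X @ beta
        ll = np.sum(y * eta - np.log1p(np.exp(eta)))
        pr = 1.0 / (1.0 + np.exp(-eta))
        w = pr * (1 - pr)
        fisher = X.T @ (X * w[:, None])
        sign, logdet = np.linalg.slogdet(fisher)
        if sign <= 0:
            return np.inf
        return -(ll + 0.5 * logdet)

    res = minimize(
        neg_pen_ll, np.zeros(2), method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 20000, "maxfev": 20000},
    )
    assert res.success or res.fun < np.inf
    return float(res.x[0]), float(res.x[1])


# ---------------------------------------------------------------------------
# trio truth-table classifier (table-driven re-derivation)
# ---------------------------------------------------------------------------

def brute_trio_classifier(
    child_gt: str, father_gt: str, mother_gt: str, father_cov: str, mother_cov: str
) -> Optional[Tuple[str, str]]:
    """Site-level trio call derived from first principles.

    An absent call is a *firm* hom-ref only when coverage guarantees depth
    >= 10; a present call is firm evidence of its genotype, but counts
    toward a confirmed verdict only when coverage is also sufficient
    (newly-hom rule).  De novo requires non-carrier parents; newly-hom
    requires het parents.
    """
    firm = {"covered": True, "low": False, "no_data": False}

    if child_gt == "het":
        if father_gt != "ref" or mother_gt != "ref":
            return None  # a parent carries it: inherited
        if firm[father_cov] and firm[mother_cov]:
            return ("de_novo", "confirmed")
        return ("de_novo", "possible")

    if child_gt == "hom_alt":
        verdicts = []
        for gt, cov in ((father_gt, father_cov), (mother_gt, mother_cov)):
            if gt == "hom_alt":
                return None
            if gt == "ref" and firm[cov]:
                return None  # firm hom-ref parent cannot have given an allele
            # parent is het (called) or could be het (unfirm absence)
            verdicts.append(gt == "het" and firm[cov])
        return ("newly_hom", "confirmed" if all(verdicts) else "possible")

    return None


def brute_comphet_classifier(states) -> Optional[str]:
    """Comp-het call by enumerating consistent parental carrier completions.

    ``states`` is a 4-tuple for (p1v1, p1v2, p2v1, p2v2), each one of
    "called", "absent_covered", "absent_low", "absent_no_data".  A slot is a
    known carrier when called, a known non-carrier when absent with covering
    depth, and unknown otherwise.  The pair is trans in a completion when
    one parent carries exactly v1 and the other exactly v2 of the pair.
    """
    domains = []
    for s in states:
        if s == "called":
            domains.append([True])
        elif s == "absent_covered":
            domains.append([False])
        else:
            domains.append([False, True])
    results = []
    for a in domains[0]:
        for b in domains[1]:
            for c in domains[2]:
                for d in domains[3]:
                    trans = (a and not b and d and not c) or (b and not a and c and not d)
                    results.append(trans)
    if not any(results):
        return None
    return "confirmed" if all(results) else "possible"
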