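"""Independent brute-force oracles used by the test suite.

The Fst oracle expands every diploid genotype into two explicit 0/1 gamete
indicators and runs a literal two-level nested ANOVA (populations /
individuals within populations / gametes within individuals) with explicit
sums over gametes. It shares no code with the package's closed-form
implementation.
"""

from __future__ import annotations

import math


def gamete_expansion_fst(pops: list[list[int]]) -> dict[str, float]:
    """Literal nested-ANOVA Fst from per-population dosage lists (0/1/2).

    Missing calls must already be removed. Returns a dict with msp, msi,
    msg, n_c and fst (fst is NaN when undefined).
    """
    pops = [list(p) for p in pops if len(p) > 0]
    n = len(pops)
    if n < 2:
        return {k: math.nan for k in ("msp", "msi", "msg", "n_c", "fst")}

    # expand: gametes[i][j] = (y1, y2) indicator pair for individual j of pop i
    gametes = [[(1 if d >= 1 else 0, 1 if d == 2 else 0) for d in p] for p in pops]
    sizes = [len(p) for p in pops]
    s1 = sum(sizes)
    s2 = sum(s * s for s in sizes)
    n_c = (s1 - s2 / s1) / (n - 1)

    all_g = [y for pop in gametes for pair in pop for y in pair]
    grand = sum(all_g) / len(all_g)

    ssp = ssi = ssg = 0.0
    for pop in gametes:
        pop_vals = [y for pair in pop for y in pair]
        pop_mean = sum(pop_vals) / len(pop_vals)
        ssp += len(pop_vals) * (pop_mean - grand) ** 2
        for pair in pop:
            ind_mean = sum(pair) / 2.0
            ssi += 2.0 * (ind_mean - pop_mean) ** 2
            for y in pair:
                ssg += (y - ind_mean) ** 2

    if s1 - n <= 0:
        return {"msp": math.nan, "msi": math.nan, "msg": math.nan,
                "n_c": n_c, "fst": math.nan}
    msp = ssp / (n - 1)
    msi = ssi / (s1 - n)
    msg = ssg / s1
    denom = msp + (n_c - 1.0) * msi + n_c * msg
    fst = (msp - msi) / denom if denom != 0.0 else math.nan
    return {"msp": msp, "msi": msi, "msg": msg, "n_c": n_c, "fst": fst}


def brute_force_outliers(values: list[float], q: float) -> tuple[float, int]:
    """Threshold and outlier count by exhaustive enumeration of the sorted
    list: threshold = element at 1-based rank ceil(q*N); count values
    strictly greater."""
    vals = sorted(values)
    n = len(vals)
    rank = math.ceil(q * n)
    thr = vals[min(max(rank, 1), n) - 1]
    return thr, sum(1 for v in vals if v > thr)
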