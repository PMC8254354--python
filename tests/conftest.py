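import math

import numpy as np
import pytest

from sexscan.synthetic_data import SimParams, make_fixture


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic cohort shared across tests (deterministic)."""
    return make_fixture(11)


@pytest.fixture(scope="session")
def small_params():
    """A small, fast layout for tests that re-simulate repeatedly."""
    return SimParams(scaffold_lengths=(3000, 2500, 1000), shared_locus_offset=800, w_locus_offset=700)


# ---------------------------------------------------------------------------
# independent oracles


def welch_oracle(a, b):
    """Closed-form Welch statistic with the p-value obtained by numerical
    quadrature of the Student-t density (independent of scipy.stats.t)."""
    from scipy.integrate import quad
    from scipy.special import gammaln

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = len(a), len(b)
    va = a.var(ddof=1) / na
    vb = b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))

    lognorm = gammaln((df + 1) / 2) - gammaln(df / 2) - 0.5 * math.log(df * math.pi)

    def density(x):
        return math.exp(lognorm - (df + 1) / 2 * math.log1p(x * x / df))

    tail, _err = quad(density, abs(t), math.inf, epsabs=1e-14, epsrel=1e-13, limit=300)
    return t, df, 2.0 * tail


def brute_force_runs(positions, statuses, target, merge_gap, min_len):
    """Region enumeration by pairwise clustering, written independently of
    merge_calls: link every pair of target positions within merge_gap + 1,
    take connected components, keep spans of at least min_len."""
    targets = sorted(p for p, s in zip(positions, statuses) if s == target)
    components = []
    for p in targets:
        placed = False
        for comp in components:
            if any(abs(p - q) - 1 <= merge_gap for q in comp):
                comp.add(p)
                placed = True
                break
        if not placed:
            components.append({p})
    # merge components bridged by later additions
    changed = True
    while changed:
        changed = False
        for i in range(len(components)):
            for j in range(i + 1, len(components)):
                if any(
                    abs(p - q) - 1 <= merge_gap
                    for p in components[i]
                    for q in components[j]
                ):
                    components[i] |= components[j]
                    del components[j]
                    changed = True
                    break
            if changed:
                break
    spans = sorted((min(c), max(c)) for c in components)
    return [(s, e) for s, e in spans if e - s + 1 >= min_len]


def enumerate_alignments(a, b, scoring):
    """Exhaustive maximum over all global alignments with affine gap costs
    (gap of length L costs open + (L-1)*extend). Exponential; tiny inputs
    only."""
    best = [-math.inf]

    def recurse(i, j, score, state):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            recurse(i + 1, j + 1, score + s, "M")
        if i < len(a):
            cost = scoring.gap_extend if state == "X" else scoring.gap_open
            recurse(i + 1, j, score + cost, "X")
        if j < len(b):
            cost = scoring.gap_extend if state == "Y" else scoring.gap_open
            recurse(i, j + 1, score + cost, "Y")

    recurse(0, 0, 0, "M")
    return best[0]


@pytest.fixture(scope="session")
def oracles():
    return {
        "welch": welch_oracle,
        "runs": brute_force_runs,
        "align": enumerate_alignments,
    }
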