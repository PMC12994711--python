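import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(0)


# ---------------------------------------------------------------------------
# independent oracles, deliberately written from the definitions rather than
# the package's formulas
# ---------------------------------------------------------------------------


def haplotype_matrix(derived_counts, n, rng):
    """Explicit 0/1 haplotype matrix realizing the given derived counts."""
    S = len(derived_counts)
    mat = np.zeros((n, S), dtype=int)
    for j, x in enumerate(derived_counts):
        carriers = rng.choice(n, size=x, replace=False)
        mat[carriers, j] = 1
    return mat


def brute_force_pi(mat):
    """Mean pairwise Hamming distance over all haplotype pairs."""
    n = mat.shape[0]
    total = 0
    pairs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += int(np.sum(mat[i] != mat[j]))
            pairs += 1
    return total / pairs


def definitional_theta_h(derived_counts, n):
    return sum(2 * x * x for x in derived_counts) / (n * (n - 1))


def reference_tajimas_d(derived_counts, n):
    """Stand-alone Tajima's D from the printed normalization constants."""
    S = len(derived_counts)
    if S == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    pi_val = sum(2.0 * x * (n - x) for x in derived_counts) / (n * (n - 1))
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        return float("nan")
    return (pi_val - S / a1) / var**0.5


def reference_fay_wu_h(derived_counts, n):
    if not derived_counts:
        return float("nan")
    pi_val = sum(2.0 * x * (n - x) for x in derived_counts) / (n * (n - 1))
    return pi_val - definitional_theta_h(derived_counts, n)


def consensus_oracle(rows, rule):
    """Set-algebra consensus: filter per method, count per column, threshold."""
    passing = {}
    for method, column, score, direction in rows:
        if direction != "positive" or method == "SLAC":
            continue
        ok = {
            "BEB": score >= rule.beb_min,
            "FUBAR": score >= rule.fubar_min,
            "MEME": score < rule.meme_max_p,
            "FEL": score < rule.fel_max_p,
        }[method]
        if ok:
            passing.setdefault(column, set()).add(method)
    return sorted(c for c, ms in passing.items() if len(ms) >= rule.min_methods)


def kendall_tau_b_oracle(x, y):
    """O(n^2) concordant/discordant pair count with tie correction."""
    n = len(x)
    concordant = discordant = tx = ty = 0
    for i in range(n):
        for j in range(i + 1, n):
            dx = x[i] - x[j]
            dy = y[i] - y[j]
            if dx == 0 and dy == 0:
                continue
            if dx == 0:
                tx += 1
            elif dy == 0:
                ty += 1
            elif dx * dy > 0:
                concordant += 1
            else:
                discordant += 1
    denom = ((concordant + discordant + tx) * (concordant + discordant + ty)) ** 0.5
    return (concordant - discordant) / denom
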