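"""Independent brute-force oracles used by the test suite.

These deliberately avoid the library code paths they check: sums of
squares by explicit loops over cell means, epsilon via an eigenvalue
identity on a Helmert-contrast covariance, and t-tail probabilities by
numeric quadrature of the density.
"""

import math

import numpy as np
from scipy.integrate import quad


def anova_ss_oracle(y: np.ndarray) -> dict:
    """Seven sums of squares and F statistics via explicit summation."""
    n, a, b = y.shape
    grand = 0.0
    for s in range(n):
        for i in range(a):
            for j in range(b):
                grand += y[s, i, j]
    grand /= n * a * b

    m_s = [sum(y[s, i, j] for i in range(a) for j in range(b)) / (a * b) for s in range(n)]
    m_a = [sum(y[s, i, j] for s in range(n) for j in range(b)) / (n * b) for i in range(a)]
    m_b = [sum(y[s, i, j] for s in range(n) for i in range(a)) / (n * a) for j in range(b)]
    m_sa = [[sum(y[s, i, j] for j in range(b)) / b for i in range(a)] for s in range(n)]
    m_sb = [[sum(y[s, i, j] for i in range(a)) / a for j in range(b)] for s in range(n)]
    m_ab = [[sum(y[s, i, j] for s in range(n)) / n for j in range(b)] for i in range(a)]

    ss_subject = a * b * sum((m_s[s] - grand) ** 2 for s in range(n))
    ss_a = n * b * sum((m_a[i] - grand) ** 2 for i in range(a))
    ss_b = n * a * sum((m_b[j] - grand) ** 2 for j in range(b))
    ss_ab = n * sum(
        (m_ab[i][j] - m_a[i] - m_b[j] + grand) ** 2 for i in range(a) for j in range(b)
    )
    ss_as = b * sum(
        (m_sa[s][i] - m_s[s] - m_a[i] + grand) ** 2 for s in range(n) for i in range(a)
    )
    ss_bs = a * sum(
        (m_sb[s][j] - m_s[s] - m_b[j] + grand) ** 2 for s in range(n) for j in range(b)
    )
    ss_abs = sum(
        (
            y[s, i, j]
            - m_sa[s][i]
            - m_sb[s][j]
            - m_ab[i][j]
            + m_s[s]
            + m_a[i]
            + m_b[j]
            - grand
        )
        ** 2
        for s in range(n)
        for i in range(a)
        for j in range(b)
    )
    ss_total = sum(
        (y[s, i, j] - grand) ** 2 for s in range(n) for i in range(a) for j in range(b)
    )

    f_time = (ss_a / (a - 1)) / (ss_as / ((a - 1) * (n - 1)))
    f_sleep = (ss_b / (b - 1)) / (ss_bs / ((b - 1) * (n - 1)))
    f_int = (ss_ab / ((a - 1) * (b - 1))) / (ss_abs / ((a - 1) * (b - 1) * (n - 1)))
    return {
        "subject": ss_subject,
        "time": ss_a,
        "sleep": ss_b,
        "time_x_sleep": ss_ab,
        "time_x_subject": ss_as,
        "sleep_x_subject": ss_bs,
        "time_x_sleep_x_subject": ss_abs,
        "ss_total": ss_total,
        "f_time": f_time,
        "f_sleep": f_sleep,
        "f_int": f_int,
    }


def helmert_contrasts(k: int) -> np.ndarray:
    """Normalized Helmert contrast rows, orthonormal and orthogonal to 1."""
    C = np.zeros((k - 1, k))
    for i in range(1, k):
        C[i - 1, :i] = 1.0
        C[i - 1, i] = -i
        C[i - 1] /= math.sqrt(i + i * i)
    return C


def gg_epsilon_eigen_oracle(scores: np.ndarray) -> float:
    """Epsilon via the eigenvalues of the contrast covariance."""
    n, k = scores.shape
    S = np.cov(scores, rowvar=False, ddof=1)
    C = helmert_contrasts(k)
    M = C @ S @ C.T
    lam = np.linalg.eigvalsh(M)
    eps = lam.sum() ** 2 / ((k - 1) * (lam**2).sum())
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def t_pvalue_quadrature_oracle(diffs: np.ndarray) -> tuple[float, float]:
    """(t, two-sided p) for a paired test, the tail by quadrature."""
    d = np.asarray(diffs, dtype=float)
    n = d.size
    mean = d.sum() / n
    var = ((d - mean) ** 2).sum() / (n - 1)
    t = mean / math.sqrt(var / n)
    nu = n - 1

    def pdf(x: float) -> float:
        c = math.gamma((nu + 1) / 2) / (math.sqrt(nu * math.pi) * math.gamma(nu / 2))
        return c * (1 + x * x / nu) ** (-(nu + 1) / 2)

    tail, _err = quad(pdf, abs(t), np.inf)
    return t, 2.0 * tail
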