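"""Repeated-measures inference: two-factor within-subject ANOVA with
Mauchly's sphericity test, Greenhouse-Geisser correction, partial eta
squared, and Tukey HSD post hocs.

The SS decomposition is the classical fully-within two-factor design: each
effect (A, B, AxB) is tested against its own effect-by-subject interaction.
eta_p^2 = SS_effect / (SS_effect + SS_residual); the Greenhouse-Geisser
epsilon is (sum lambda)^2 / (d * sum lambda^2) over the eigenvalues of the
effect's contrast-space covariance, and degrees of freedom are multiplied by
epsilon when Mauchly's test rejects sphericity (alpha configurable).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    name: str
    F: float
    df_effect: float
    df_residual: float
    df_effect_corr: float
    df_residual_corr: float
    p_uncorrected: float
    p: float
    ss_effect: float
    ss_residual: float
    eta_p_sq: float
    epsilon_gg: float
    mauchly_w: float
    mauchly_p: float
    sphericity_corrected: bool


@dataclass
class RmAnovaTable:
    effects: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects.values()]).set_index("name")

    def to_dict(self) -> dict:
        return {k: {kk: (float(vv) if isinstance(vv, (int, float, np.floating)) else vv)
                    for kk, vv in vars(e).items() if kk != "name"}
                for k, e in self.effects.items()}


# ---------------------------------------------------------------------------
# epsilon / Mauchly
# ---------------------------------------------------------------------------

def greenhouse_geisser_epsilon(covariance_of_levels: np.ndarray) -> float:
    """GG epsilon from the double-centered level covariance, clamped to [1/(k-1), 1]."""
    S = np.asarray(covariance_of_levels, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-10 * max(1.0, np.abs(S).max())):
        raise ValueError("covariance must be symmetric")
    k = S.shape[0]
    if k < 2:
        raise ValueError("need at least two levels")
    J = np.eye(k) - np.ones((k, k)) / k
    D = J @ S @ J
    lam = np.clip(linalg.eigvalsh(D), 0.0, None)
    denom = (k - 1) * np.sum(lam ** 2)
    if denom <= 0:
        return 1.0
    eps = float(np.sum(lam) ** 2 / denom)
    return float(np.clip(eps, 1.0 / (k - 1), 1.0))


def _contrast_epsilon_mauchly(Y: np.ndarray, C: np.ndarray) -> tuple[float, float, float]:
    """epsilon, Mauchly W and p for contrast matrix C (d x k) applied to
    subject-by-level data Y (n x k)."""
    n, k = Y.shape
    d = C.shape[0]
    if d < 1:
        return 1.0, 1.0, 1.0
    Z = Y @ C.T                                # n x d
    S = np.cov(Z, rowvar=False, ddof=1)
    S = np.atleast_2d(S)
    lam = np.clip(linalg.eigvalsh(S), 0.0, None)
    sum_l, sum_l2 = lam.sum(), (lam ** 2).sum()
    eps = 1.0 if sum_l2 <= 0 else float(np.clip(sum_l ** 2 / (d * sum_l2), 1.0 / d, 1.0))
    if d == 1:
        return eps, 1.0, 1.0
    tr = np.trace(S)
    det = float(np.prod(lam[lam > 0])) if np.all(lam > 0) else float(linalg.det(S))
    if tr <= 0 or det <= 0:
        return eps, 0.0, 0.0
    W = det / (tr / d) ** d
    W = float(min(max(W, 1e-300), 1.0))
    df = d * (d + 1) // 2 - 1
    if n - 1 <= 0 or df <= 0:
        return eps, W, 1.0
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * np.log(W)
    p = float(sps.chi2.sf(max(chi2, 0.0), df))
    return eps, W, p


def mauchly_test(level_data: np.ndarray) -> dict:
    """Mauchly's sphericity test on subject x level data (chi-square approximation)."""
    Y = np.asarray(level_data, dtype=float)
    if Y.ndim != 2:
        raise ValueError("level_data must be subjects x levels")
    n, k = Y.shape
    if k < 2:
        raise ValueError("need at least two levels")
    if k == 2:
        return {"W": 1.0, "p": 1.0}
    if n <= k - 1:
        raise ValueError("need more subjects than levels minus one")
    C = linalg.helmert(k)
    _, W, p = _contrast_epsilon_mauchly(Y, C)
    return {"W": W, "p": p}


# ---------------------------------------------------------------------------
# two-way repeated-measures ANOVA
# ---------------------------------------------------------------------------

def rm_anova_two_way(data: np.ndarray,
                     factor_names: tuple[str, str] = ("A", "B"),
                     gg_alpha: float = 0.05) -> RmAnovaTable:
    """Fully-within two-factor ANOVA on a subjects x a x b value grid.

    GG-corrected dfs and p are reported for an effect when its Mauchly test
    rejects sphericity at ``gg_alpha`` (set ``gg_alpha=1`` to always correct,
    ``0`` to never).
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 3:
        raise ValueError("data must be subjects x factorA x factorB")
    if np.any(~np.isfinite(X)):
        raise ValueError("missing cells are not supported (complete balanced grid required)")
    n, a, b = X.shape
    if n < 3:
        raise ValueError("need at least three subjects")
    if a < 2 or b < 2:
        raise ValueError("each factor needs at least two levels")

    g = X.mean()
    A_i = X.mean(axis=(0, 2))          # a
    B_j = X.mean(axis=(0, 1))          # b
    cell = X.mean(axis=0)              # a x b
    subj = X.mean(axis=(1, 2))         # n
    m_si = X.mean(axis=2)              # n x a
    m_sj = X.mean(axis=1)              # n x b

    ss_A = n * b * np.sum((A_i - g) ** 2)
    ss_errA = b * np.sum((m_si - A_i[None, :] - subj[:, None] + g) ** 2)
    ss_B = n * a * np.sum((B_j - g) ** 2)
    ss_errB = a * np.sum((m_sj - B_j[None, :] - subj[:, None] + g) ** 2)
    ss_AB = n * np.sum((cell - A_i[:, None] - B_j[None, :] + g) ** 2)
    resid = (X - m_si[:, :, None] - m_sj[:, None, :] - cell[None, :, :]
             + A_i[None, :, None] + B_j[None, None, :] + subj[:, None, None] - g)
    ss_errAB = np.sum(resid ** 2)

    Ha, Hb = linalg.helmert(a), linalg.helmert(b)
    ONEa, ONEb = np.ones((1, a)) / a, np.ones((1, b)) / b
    Yflat = X.reshape(n, a * b)
    specs = [
        (factor_names[0], ss_A, ss_errA, a - 1, (a - 1) * (n - 1), np.kron(Ha, ONEb)),
        (factor_names[1], ss_B, ss_errB, b - 1, (b - 1) * (n - 1), np.kron(ONEa, Hb)),
        (f"{factor_names[0]}*{factor_names[1]}", ss_AB, ss_errAB,
         (a - 1) * (b - 1), (a - 1) * (b - 1) * (n - 1), np.kron(Ha, Hb)),
    ]

    ss_total = float(np.sum((X - g) ** 2))
    tiny = 1e-12 * max(ss_total, np.finfo(float).tiny)

    table = RmAnovaTable()
    for name, ss_e, ss_r, df_e, df_r, C in specs:
        if ss_e < tiny:                         # exact null effect (float noise)
            ss_e = 0.0
        ms_e, ms_r = ss_e / df_e, ss_r / df_r
        F = 0.0 if (ss_e == 0 or ms_r == 0) else float(ms_e / ms_r)
        p_unc = float(sps.f.sf(F, df_e, df_r)) if F > 0 else 1.0
        eps, W, p_m = _contrast_epsilon_mauchly(Yflat, C)
        corrected = bool(p_m < gg_alpha and df_e > 1)
        df_e_c = df_e * eps if corrected else float(df_e)
        df_r_c = df_r * eps if corrected else float(df_r)
        p = float(sps.f.sf(F, df_e_c, df_r_c)) if F > 0 else 1.0
        eta = ss_e / (ss_e + ss_r) if (ss_e + ss_r) > 0 else 0.0
        table.effects[name] = EffectResult(
            name=name, F=F, df_effect=float(df_e), df_residual=float(df_r),
            df_effect_corr=float(df_e_c), df_residual_corr=float(df_r_c),
            p_uncorrected=p_unc, p=p, ss_effect=float(ss_e), ss_residual=float(ss_r),
            eta_p_sq=float(eta), epsilon_gg=float(eps), mauchly_w=float(W),
            mauchly_p=float(p_m), sphericity_corrected=corrected,
        )
        # internal consistency: eta_p^2 must satisfy the F/df identity
        assert abs(table.effects[name].eta_p_sq
                   - eta_p_sq_from_f(max(F, 0.0), df_e, df_r)) < 1e-10
    return table


def eta_p_sq_from_f(F: float, df_effect: float, df_residual: float) -> float:
    """Partial eta squared from F and its degrees of freedom."""
    if df_effect <= 0 or df_residual <= 0:
        raise ValueError("degrees of freedom must be positive")
    if F < 0:
        raise ValueError("F must be non-negative")
    return float(F * df_effect / (F * df_effect + df_residual))


# ---------------------------------------------------------------------------
# post hocs
# ---------------------------------------------------------------------------

def tukey_hsd(level_means, ms_residual: float, df_residual: float,
              n_per_level: int, level_names=None, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD for all level pairs via the studentized range distribution.

    In the repeated-measures context ``ms_residual`` is the within-subject
    residual mean square of the relevant effect.
    """
    means = np.asarray(level_means, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least two levels")
    if df_residual <= 0:
        raise ValueError("df_residual must be positive")
    if level_names is None:
        level_names = [f"L{i}" for i in range(k)]
    se = np.sqrt(ms_residual / n_per_level)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        q = abs(diff) / se if se > 0 else np.inf
        p = float(sps.studentized_range.sf(q, k, df_residual)) if np.isfinite(q) else 0.0
        p = min(max(p, 0.0), 1.0)
        rows.append({"level_1": level_names[i], "level_2": level_names[j],
                     "mean_diff": float(diff), "p_adj": p, "significant": p < alpha})
    return pd.DataFrame(rows)


def pairwise_contrast_anovas(data: np.ndarray, factor_a_levels: list[str],
                             factor_names: tuple[str, str] = ("modality", "bin"),
                             gg_alpha: float = 0.05, alpha: float = 0.05) -> list[dict]:
    """Separate 2 x B rm-ANOVAs for every pair of factor-A levels.

    Returns, per pair, the ANOVA table plus per-bin paired-t significance
    flags (the per-trial-count contrast markers used for plotting).
    """
    X = np.asarray(data, dtype=float)
    n, a, b = X.shape
    if len(factor_a_levels) != a:
        raise ValueError("level names do not match the factor-A dimension")
    out = []
    for i, j in combinations(range(a), 2):
        sub = X[:, [i, j], :]
        table = rm_anova_two_way(sub, factor_names=factor_names, gg_alpha=gg_alpha)
        per_bin = []
        for bb in range(b):
            t, p = sps.ttest_rel(sub[:, 0, bb], sub[:, 1, bb])
            per_bin.append({"bin_index": bb, "t": float(t), "p": float(p),
                            "significant": bool(p < alpha)})
        out.append({"pair": (factor_a_levels[i], factor_a_levels[j]),
                    "anova": table, "per_bin": per_bin})
    return out
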