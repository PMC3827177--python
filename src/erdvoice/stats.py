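"""Within-subject statistics: repeated-measures ANOVA with
Greenhouse–Geisser correction, post-hoc tests, Wilcoxon signed-rank,
Spearman correlation with a permutation p-value, and stimulus-feature
multiple regression.

The rm-ANOVA uses the orthonormal-contrast formulation: for each effect, an
orthonormal basis (Kronecker product of per-factor Helmert contrasts, and
uniform averaging vectors for factors not in the effect) maps each
participant's cell vector to effect scores; effect and error sums of
squares are the between- and within-participant variation of those scores,
and the Greenhouse–Geisser epsilon is tr(S)^2 / (df * tr(S^2)) for S the
covariance of the scores.  For a two-level factor epsilon is exactly 1 and
the correction is a no-op.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import studentized_range


# ---------------------------------------------------------------------------
# repeated-measures ANOVA

@dataclass
class EffectResult:
    name: str
    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float
    p_gg: float
    ss_effect: float
    ss_error: float


@dataclass
class AnovaResult:
    effects: dict                      # name -> EffectResult
    cell_means: pd.Series
    n_subjects: int
    factor_levels: dict                # factor -> list of levels
    error_terms: dict = field(default_factory=dict)  # name -> (MS_err, df_err)

    def __getitem__(self, name: str) -> EffectResult:
        return self.effects[name]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (e.name, e.F, e.df1, e.df2, e.p, e.gg_epsilon, e.p_gg)
            for e in self.effects.values()
        ]
        return pd.DataFrame(
            rows, columns=["effect", "F", "df1", "df2", "p", "gg_epsilon", "p_gg"]
        )


def _helmert(k: int) -> np.ndarray:
    """Orthonormal contrast basis (k x k-1)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.linalg.norm(h[:, j - 1])
    return h


def rm_anova(table: pd.DataFrame, dv: str, subject: str, within) -> AnovaResult:
    """Fully within-subject ANOVA on a long-format table.

    Parameters
    ----------
    table : DataFrame
        Long format with one row per (subject, cell).
    dv, subject : str
        Column names of the dependent variable and the subject id.
    within : list of str
        Up to three within-subject factor columns.

    All subject x cell combinations must be present exactly once
    (balanced); subjects with missing cells must be excluded beforehand.
    """
    within = list(within)
    if not 1 <= len(within) <= 3:
        raise ValueError("1 to 3 within factors supported")
    levels = {f: sorted(table[f].unique()) for f in within}
    shape = [len(levels[f]) for f in within]
    subjects = sorted(table[subject].unique())
    n = len(subjects)
    if n < 2:
        raise ValueError("need at least 2 subjects")

    pivot = table.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    full_cols = (
        pd.MultiIndex.from_product([levels[f] for f in within], names=within)
        if len(within) > 1 else pd.Index(levels[within[0]], name=within[0])
    )
    pivot = pivot.reindex(columns=full_cols)
    if pivot.isna().any().any():
        bad = pivot.isna().sum().sum()
        raise ValueError(f"unbalanced design: {bad} missing subject x cell values")
    X = pivot.to_numpy(float)  # n_subjects x n_cells (C order over factors)

    cell_means = pivot.mean(axis=0)
    bases = {f: _helmert(len(levels[f])) for f in within}
    unif = {f: np.full((len(levels[f]), 1), 1.0 / np.sqrt(len(levels[f]))) for f in within}

    effects = {}
    error_terms = {}
    for r in range(1, len(within) + 1):
        for combo in combinations(within, r):
            M = np.ones((1, 1))
            for f in within:
                M = np.kron(M, bases[f] if f in combo else unif[f])
            Y = X @ M                     # n x df1 effect scores
            df1 = Y.shape[1]
            ybar = Y.mean(axis=0)
            ss_eff = n * float(ybar @ ybar)
            resid = Y - ybar
            ss_err = float((resid**2).sum())
            df2 = (n - 1) * df1
            ms_eff = ss_eff / df1
            ms_err = ss_err / df2
            F = ms_eff / ms_err if ms_err > 0 else 0.0
            p = float(sps.f.sf(F, df1, df2)) if ms_err > 0 else 1.0
            if df1 > 1:
                S = np.cov(Y, rowvar=False)
                tr, tr2 = float(np.trace(S)), float(np.trace(S @ S))
                eps = tr**2 / (df1 * tr2) if tr2 > 0 else 1.0
                eps = float(np.clip(eps, 1.0 / df1, 1.0))
            else:
                eps = 1.0
            p_gg = float(sps.f.sf(F, df1 * eps, df2 * eps)) if ms_err > 0 else 1.0
            name = "*".join(combo)
            effects[name] = EffectResult(
                name, F, df1, df2, p, eps, max(p_gg, p), ss_eff, ss_err
            )
            error_terms[name] = (ms_err, df2)
    return AnovaResult(
        effects=effects, cell_means=cell_means, n_subjects=n,
        factor_levels=levels, error_terms=error_terms,
    )


# ---------------------------------------------------------------------------
# post-hoc tests

def posthoc(
    anova: AnovaResult,
    effect: str,
    method: str = "tukey_hsd",
) -> pd.DataFrame:
    """All pairwise comparisons among the cells of a (possibly interaction)
    effect, using that effect's ANOVA error term.

    ``tukey_hsd`` uses the studentized range distribution; ``fisher_lsd``
    an unadjusted t-test on the same error term (hence LSD p <= HSD p).
    """
    if method not in ("tukey_hsd", "fisher_lsd"):
        raise ValueError(f"unknown post-hoc method {method!r}")
    if effect not in anova.error_terms:
        raise ValueError(f"effect {effect!r} not in ANOVA")
    ms_err, df_err = anova.error_terms[effect]
    factors = effect.split("*")
    means = anova.cell_means
    if isinstance(means.index, pd.MultiIndex):
        names = list(means.index.names)
        keep = [names.index(f) for f in factors]
        grouped = means.groupby(level=keep).mean()
    else:
        grouped = means
    cells = list(grouped.index)
    k = len(cells)
    n = anova.n_subjects
    rows = []
    for a, b in combinations(range(k), 2):
        diff = float(grouped.iloc[a] - grouped.iloc[b])
        se = np.sqrt(ms_err / n)
        if method == "tukey_hsd":
            q = abs(diff) / se
            p = float(studentized_range.sf(q, k, df_err)) if se > 0 else 1.0
        else:
            t = abs(diff) / (se * np.sqrt(2.0))
            p = float(2 * sps.t.sf(t, df_err)) if se > 0 else 1.0
        rows.append((cells[a], cells[b], diff, min(p, 1.0)))
    return pd.DataFrame(rows, columns=["cell_a", "cell_b", "diff", "p"])


# ---------------------------------------------------------------------------
# nonparametric tests and correlation

def wilcoxon_paired(x, y):
    """Paired Wilcoxon signed-rank test; exact null for n <= 25.

    Returns ``(W, p)`` where W is the smaller signed-rank sum, matching the
    conventional report.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 5:
        raise ValueError("need paired samples with n >= 5")
    d = x - y
    if np.all(d == 0):
        # identical pairs carry no evidence either way
        return 0.0, 1.0
    nz = d[d != 0]
    zero_method = "wilcox" if len(nz) == len(d) else "zsplit"
    mode = "exact" if len(nz) == len(d) and len(nz) <= 25 else "approx"
    res = sps.wilcoxon(x, y, zero_method=zero_method, mode=mode)
    return float(res.statistic), float(res.pvalue)


@dataclass
class CorrelationResult:
    rho: float
    n: int
    p: float
    n_permutations: int


def spearman(x, y, n_permutations: int = 10_000, rng_seed=0) -> CorrelationResult:
    """Spearman rank correlation with a seeded permutation p-value.

    Midranks handle ties; the two-sided p is the fraction of label
    permutations whose |rho| meets or exceeds the observed one (add-one
    estimator).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    rng = np.random.default_rng(rng_seed)
    rxc = (rx - rx.mean()) / (rx.std() * np.sqrt(len(x)))
    ryc = (ry - ry.mean()) / (ry.std() * np.sqrt(len(y)))
    perms = np.array([rng.permutation(len(x)) for _ in range(n_permutations)])
    rho_null = ryc[perms] @ rxc
    p = (1 + np.sum(np.abs(rho_null) >= abs(rho) - 1e-12)) / (n_permutations + 1)
    return CorrelationResult(rho=rho, n=len(x), p=float(p), n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# stimulus-feature regression

def feature_regression(descriptors: pd.DataFrame, response, predictors=None):
    """OLS of per-stimulus mean band power on acoustic descriptors.

    Returns a dict with overall R², F, df, p and per-coefficient t and p.
    Warns (via the returned ``condition_number``) when the design is badly
    conditioned.
    """
    import statsmodels.api as sm

    predictors = predictors if predictors is not None else list(descriptors.columns)
    if len(descriptors) < 10:
        raise ValueError("need at least 10 stimuli")
    X = sm.add_constant(descriptors[predictors].to_numpy(float))
    yv = np.asarray(response, float)
    fit = sm.OLS(yv, X).fit()
    return {
        "r2": float(fit.rsquared),
        "F": float(fit.fvalue),
        "df_model": int(fit.df_model),
        "df_resid": int(fit.df_resid),
        "p": float(fit.f_pvalue),
        "coef": dict(zip(["const"] + predictors, map(float, fit.params))),
        "t": dict(zip(["const"] + predictors, map(float, fit.tvalues))),
        "coef_p": dict(zip(["const"] + predictors, map(float, fit.pvalues))),
        "condition_number": float(np.linalg.cond(X)),
    }
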