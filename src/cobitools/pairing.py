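"""Binomial-GLM analysis of chromosome-specific meiotic bivalent formation.

The response in each (chromosome, individual) cell is the number of
metaphase-I spermatocytes in which the chromosome formed a bivalent
versus appeared as univalents.  A logistic model with factors for
chromosome identity, individual, and optionally their interaction is
fitted by iteratively reweighted least squares on the grouped binomial
counts.  Effects are tested by likelihood-ratio (deviance) tests —
more reliable than Wald tests when a chromosome pairs in almost no
cells — and all pairwise chromosome contrasts on the log-odds scale
(averaged over individuals with equal weights) are Bonferroni-adjusted.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats


@dataclass
class GlmFit:
    """A fitted grouped-binomial logistic model (treatment coding)."""

    model: str
    params: pd.Series
    cov: pd.DataFrame
    deviance: float
    df_resid: int
    converged: bool
    chrom_levels: list[str]
    indiv_levels: list[str]
    fitted_probs: np.ndarray

    @property
    def n_params(self) -> int:
        return len(self.params)


_TERMS = {"1", "chromosome", "individual", "chromosome*individual", "chromosome:individual"}


def _parse_model(model: str) -> tuple[bool, bool, bool]:
    """Return (chromosome main, individual main, interaction) flags."""
    terms = [t.strip() for t in model.replace("~", "").split("+") if t.strip()]
    chrom = indiv = inter = False
    for t in terms:
        if t == "1":
            continue
        elif t == "chromosome":
            chrom = True
        elif t == "individual":
            indiv = True
        elif t in ("chromosome*individual",):
            chrom = indiv = inter = True
        elif t in ("chromosome:individual",):
            inter = True
        else:
            raise ValueError(f"unknown model term {t!r}")
    return chrom, indiv, inter


def _design(
    table: pd.DataFrame,
    chrom_levels: list[str],
    indiv_levels: list[str],
    model: str,
) -> pd.DataFrame:
    """Treatment-coded design matrix (first level of each factor is the
    reference)."""
    chrom, indiv, inter = _parse_model(model)
    n = len(table)
    cols: dict[str, np.ndarray] = {"Intercept": np.ones(n)}
    c_dum = {
        lv: (table["chromosome"] == lv).to_numpy(float) for lv in chrom_levels[1:]
    }
    i_dum = {
        lv: (table["individual"] == lv).to_numpy(float) for lv in indiv_levels[1:]
    }
    if chrom:
        for lv, col in c_dum.items():
            cols[f"chromosome[{lv}]"] = col
    if indiv:
        for lv, col in i_dum.items():
            cols[f"individual[{lv}]"] = col
    if inter:
        for clv, ccol in c_dum.items():
            for ilv, icol in i_dum.items():
                cols[f"chromosome[{clv}]:individual[{ilv}]"] = ccol * icol
    return pd.DataFrame(cols, index=table.index)


def _validate_table(table: pd.DataFrame) -> pd.DataFrame:
    need = {"chromosome", "individual", "n_paired", "n_unpaired"}
    if set(table.columns) < need:
        raise ValueError(f"pairing table must have columns {sorted(need)}")
    if ((table["n_paired"] < 0) | (table["n_unpaired"] < 0)).any():
        raise ValueError("counts must be non-negative")
    # cells with no scored spermatocytes carry no information
    return table[(table["n_paired"] + table["n_unpaired"]) > 0].reset_index(drop=True)


def fit_binomial_glm(table: pd.DataFrame, model: str = "chromosome*individual") -> GlmFit:
    """Maximum-likelihood logistic fit on grouped paired/unpaired counts.

    ``model`` names the factors to include: any of ``"1"``,
    ``"chromosome"``, ``"individual"``, ``"chromosome+individual"``,
    ``"chromosome*individual"``.  Reference levels are the alphabetically
    first chromosome and individual.  Raises on rank-deficient designs,
    naming the aliased columns.
    """
    table = _validate_table(table)
    chrom_levels = sorted(table["chromosome"].unique())
    indiv_levels = sorted(table["individual"].unique())
    X = _design(table, chrom_levels, indiv_levels, model)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the columns that add no rank, in design order
        bad, keep, rank = [], [], 0
        for name in X.columns:
            r = np.linalg.matrix_rank(X[keep + [name]].to_numpy())
            if r > rank:
                rank, keep = r, keep + [name]
            else:
                bad.append(name)
        raise ValueError(f"rank-deficient design; aliased terms: {bad}")
    endog = table[["n_paired", "n_unpaired"]].to_numpy(float)
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

    with _warnings.catch_warnings():
        # saturated designs legitimately reach df_resid == 0 / exact fits
        _warnings.simplefilter("ignore", RuntimeWarning)
        _warnings.simplefilter("ignore", PerfectSeparationWarning)
        res = sm.GLM(endog, X.to_numpy(), family=sm.families.Binomial()).fit(tol=1e-10)
    return GlmFit(
        model=model,
        params=pd.Series(res.params, index=X.columns),
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        converged=bool(res.converged),
        chrom_levels=chrom_levels,
        indiv_levels=indiv_levels,
        fitted_probs=np.asarray(res.mu),
    )


def lrt_effect(full: GlmFit, reduced: GlmFit) -> tuple[float, int, float]:
    """Likelihood-ratio test of a reduced model nested in a full model.

    Returns ``(chi-square statistic, df, p)``; the statistic is the
    deviance difference, df the parameter-count difference.
    """
    if not set(reduced.params.index) <= set(full.params.index):
        raise ValueError("models are not nested")
    df = full.n_params - reduced.n_params
    stat = max(0.0, reduced.deviance - full.deviance)
    p = 1.0 if df == 0 else float(stats.chi2.sf(stat, df))
    return stat, df, p


def chromosome_effect_test(table: pd.DataFrame) -> tuple[float, int, float]:
    """LRT of the chromosome main effect (chromosome+individual vs
    individual-only)."""
    full = fit_binomial_glm(table, "chromosome+individual")
    reduced = fit_binomial_glm(table, "individual")
    return lrt_effect(full, reduced)


def _chromosome_logodds(fit: GlmFit) -> tuple[np.ndarray, np.ndarray]:
    """Per-chromosome linear predictor averaged over individuals with
    equal weights, with its contrast-ready design rows."""
    grid = pd.DataFrame(
        [
            {"chromosome": c, "individual": i, "n_paired": 1, "n_unpaired": 1}
            for c in fit.chrom_levels
            for i in fit.indiv_levels
        ]
    )
    X = _design(grid, fit.chrom_levels, fit.indiv_levels, fit.model)
    X = X.reindex(columns=fit.params.index, fill_value=0.0)
    n_ind = len(fit.indiv_levels)
    L = np.stack(
        [
            X.to_numpy()[k * n_ind : (k + 1) * n_ind].mean(axis=0)
            for k in range(len(fit.chrom_levels))
        ]
    )
    eta = L @ fit.params.to_numpy()
    return eta, L


def pairwise_contrasts(
    table_or_fit: pd.DataFrame | GlmFit,
    model: str = "chromosome*individual",
    adjust: str = "bonferroni",
) -> pd.DataFrame:
    """All pairwise chromosome contrasts on the log-odds scale.

    Estimated marginal log-odds per chromosome are averaged over
    individuals with equal weights; contrasts use Wald standard errors
    from the fitted covariance and two-sided normal p-values, adjusted
    as ``p_adjusted = min(1, m * p_raw)`` with ``m = C(k, 2)``.
    """
    if adjust not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    fit = (
        table_or_fit
        if isinstance(table_or_fit, GlmFit)
        else fit_binomial_glm(table_or_fit, model)
    )
    if len(fit.chrom_levels) < 2:
        raise ValueError("need at least two chromosomes for contrasts")
    eta, L = _chromosome_logodds(fit)
    cov = fit.cov.to_numpy()
    pairs = list(itertools.combinations(range(len(fit.chrom_levels)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        l = L[i] - L[j]
        diff = float(eta[i] - eta[j])
        se = float(np.sqrt(l @ cov @ l))
        z = diff / se if se > 0 else np.inf * np.sign(diff)
        p = float(2 * stats.norm.sf(abs(z)))
        rows.append(
            {
                "chrom_a": fit.chrom_levels[i],
                "chrom_b": fit.chrom_levels[j],
                "log_odds_diff": diff,
                "se": se,
                "statistic": z,
                "p_raw": p,
                "p_adjusted": min(1.0, m * p) if adjust == "bonferroni" else p,
            }
        )
    return pd.DataFrame(rows)


def per_chromosome_individual_test(
    table: pd.DataFrame, chromosome: str
) -> dict[str, float]:
    """Within one chromosome, test for differences in pairing success
    among individuals (logistic fit of paired ~ individual, LRT against
    the intercept-only model)."""
    sub = _validate_table(table)
    sub = sub[sub["chromosome"] == chromosome]
    if sub["individual"].nunique() < 2:
        raise ValueError(f"chromosome {chromosome!r} scored in fewer than two individuals")
    full = fit_binomial_glm(sub, "individual")
    reduced = fit_binomial_glm(sub, "1")
    stat, df, p = lrt_effect(full, reduced)
    coefs = full.params[full.params.index.str.startswith("individual[")]
    return {
        "statistic": stat,
        "df": df,
        "p": p,
        **{name: float(v) for name, v in coefs.items()},
    }


def mosaic_table(table: pd.DataFrame) -> pd.DataFrame:
    """Per-cell pairing proportions and totals (mosaic-plot data)."""
    t = _validate_table(table).copy()
    t["n_total"] = t["n_paired"] + t["n_unpaired"]
    t["prop_paired"] = t["n_paired"] / t["n_total"]
    return t[["chromosome", "individual", "n_paired", "n_unpaired", "n_total", "prop_paired"]]
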