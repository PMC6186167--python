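"""Treatment-level inference: bootstrap group summaries, random-intercept
mixed models, and marginal/conditional R^2 from variance components."""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# bootstrap group summaries
# ---------------------------------------------------------------------------


def group_summary(
    data: pd.DataFrame,
    value: str,
    by: list[str],
    n_boot: int = 2000,
    seed: int | None = 0,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-group mean with a nonparametric percentile bootstrap CI.

    Resampling is at the row (plot) level within each group.  Groups of size
    one get undefined CIs (NaN bounds, ``ci_defined`` False).  The
    ``excludes_zero`` flag marks groups whose CI lies entirely on one side of
    zero.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    alpha = (1.0 - level) / 2.0
    rows = []
    for key, grp in data.groupby(by, sort=True):
        vals = grp[value].to_numpy(dtype=float)
        n = len(vals)
        if n == 0:
            raise ValueError(f"empty group {key}")
        mean = float(vals.mean())
        if n == 1:
            lo = hi = float("nan")
            defined = False
        else:
            idx = rng.integers(0, n, size=(n_boot, n))
            means = vals[idx].mean(axis=1)
            lo = float(np.quantile(means, alpha))
            hi = float(np.quantile(means, 1.0 - alpha))
            defined = True
        key_t = key if isinstance(key, tuple) else (key,)
        rows.append(
            dict(zip(by, key_t))
            | {
                "n": n,
                "mean": mean,
                "ci_lo": lo,
                "ci_hi": hi,
                "ci_defined": defined,
                "excludes_zero": bool(defined and (lo > 0 or hi < 0)),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mixed model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, fixed effects and the random-intercept grouping."""

    response: str
    richness_col: str = "richness"
    richness_scale: str = "log2"  # or "linear"
    myco_col: str | None = "myco_level"
    myco_reference: str = "AMF"
    group_col: str = "composition"
    block_col: str | None = None

    def __post_init__(self):
        if self.richness_scale not in ("log2", "linear"):
            raise ValueError(f"unknown richness scale {self.richness_scale!r}")


@dataclass(frozen=True)
class VarianceComponents:
    """Nakagawa-style decomposition of a random-intercept model's variance."""

    var_fixed: float
    var_random: float
    var_resid: float
    r2_marginal: float
    r2_conditional: float


@dataclass
class MixedModelResult:
    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    varcomp: VarianceComponents
    converged: bool
    singular: bool
    n_obs: int
    n_groups: int

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "var_fixed": self.varcomp.var_fixed,
            "var_random": self.varcomp.var_random,
            "var_resid": self.varcomp.var_resid,
            "r2_marginal": self.varcomp.r2_marginal,
            "r2_conditional": self.varcomp.r2_conditional,
            "converged": self.converged,
            "singular": self.singular,
            "n_obs": self.n_obs,
            "n_groups": self.n_groups,
        }


def nakagawa_r2(
    var_fixed: float, var_random: float, var_resid: float
) -> tuple[float, float]:
    """Marginal and conditional R^2 from variance components.

    Marginal: fixed-effect variance over the total; conditional: fixed plus
    random-intercept variance over the total.
    """
    comps = np.array([var_fixed, var_random, var_resid], dtype=float)
    if (comps < 0).any():
        raise ValueError("variance components must be nonnegative")
    total = comps.sum()
    if total == 0:
        raise ValueError("all variance components are zero")
    return float(var_fixed / total), float((var_fixed + var_random) / total)


def fit_mixed_model(data: pd.DataFrame, spec: ModelSpec) -> MixedModelResult:
    """REML random-intercept linear mixed model per the model spec.

    Fixed effects: (optionally log2-transformed) richness, mycorrhizal level
    (treatment coding against the configured reference) and optionally block;
    random intercept per community composition.  Wald z tests are reported
    for the fixed effects.  A near-zero random-intercept variance is flagged
    as singular rather than treated as an error.
    """
    df = data.copy()
    if spec.group_col not in df.columns:
        raise ValueError(f"missing grouping column {spec.group_col!r}")
    if df[spec.group_col].nunique() < 2:
        raise ValueError("grouping variable needs at least 2 levels")
    if spec.richness_scale == "log2":
        df["_richness"] = np.log2(df[spec.richness_col].astype(float))
    else:
        df["_richness"] = df[spec.richness_col].astype(float)
    terms = ["_richness"]
    if spec.myco_col is not None and df[spec.myco_col].nunique() > 1:
        terms.append(f"C({spec.myco_col}, Treatment('{spec.myco_reference}'))")
    if spec.block_col is not None:
        terms.append(f"C({spec.block_col})")
    formula = f"{spec.response} ~ " + " + ".join(terms)

    model = smf.mixedlm(formula, data=df, groups=df[spec.group_col])
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError("fixed-effect design matrix is rank deficient")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = model.fit(reml=True)
    if not result.converged:
        raise RuntimeError(
            "mixed model failed to converge; optimizer message: "
            f"{getattr(result, 'mle_retvals', None)}"
        )
    var_random = float(np.asarray(result.cov_re).ravel()[0])
    var_resid = float(result.scale)
    singular = var_random < 1e-8 * max(var_resid, 1e-300)
    if singular:
        logger.warning("singular fit: random-intercept variance is ~0")
    fe_names = list(model.exog_names)
    fitted_fixed = model.exog @ result.fe_params.to_numpy()
    var_fixed = float(np.var(fitted_fixed))
    r2m, r2c = nakagawa_r2(var_fixed, max(var_random, 0.0), var_resid)
    return MixedModelResult(
        params=result.fe_params.copy(),
        bse=result.bse_fe.copy(),
        pvalues=result.pvalues[fe_names].copy(),
        varcomp=VarianceComponents(
            var_fixed=var_fixed,
            var_random=var_random,
            var_resid=var_resid,
            r2_marginal=r2m,
            r2_conditional=r2c,
        ),
        converged=bool(result.converged),
        singular=singular,
        n_obs=int(model.nobs),
        n_groups=int(df[spec.group_col].nunique()),
    )
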