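"""Multi-environment phenotype analysis: variance components, BLUPs, H².

The working model for a line x environment x replicate trial is

    y_ijk = mu + env_j + g_i + (ge)_ij + e_ijk

with environment fixed and genotype (g) and genotype-by-environment
(ge) random — the standard plant-breeding model for entry-mean BLUPs.
Balanced designs are solved in closed form from expected mean squares:

    E[MS_G]  = s2_e + R s2_ge + E R s2_g
    E[MS_GE] = s2_e + R s2_ge
    E[MS_e]  = s2_e

Unbalanced designs are fitted by REML through a linear mixed model
(statsmodels MixedLM) with the same effect structure.  Negative
variance-component estimates are truncated at zero and flagged.

Entry-mean broad-sense heritability follows

    H^2 = s2_g / (s2_g + s2_ge / E + s2_e / (E R)),

and the balanced-case BLUP of line *i* is the shrunken line-mean
deviation  lambda (ybar_i - ybar)  with
lambda = s2_g / (s2_g + s2_ge / E + s2_e / (E R)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_ge: float
    sigma2_e: float
    n_env: int
    n_rep: float  # mean replicates per line x environment cell
    n_lines: int
    method: str = "moments"
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("sigma2_g", "sigma2_ge", "sigma2_e"):
            v = getattr(self, name)
            if v < 0:
                setattr(self, name, 0.0)
                self.flags.append(f"{name} truncated at 0 (was {v:.4g})")


def _trait_table(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    sub = table[table["trait"] == trait].dropna(subset=["value"])
    if sub.empty:
        raise ValueError(f"no observations for trait {trait!r}")
    return sub


def _is_balanced(sub: pd.DataFrame) -> bool:
    counts = sub.groupby(["line", "env"], observed=True).size()
    n_lines = sub["line"].nunique()
    n_env = sub["env"].nunique()
    return len(counts) == n_lines * n_env and counts.nunique() == 1


def fit_variance_components(table: pd.DataFrame, trait: str,
                            include_ge: bool = True) -> VarianceComponents:
    """Estimate (s2_g, s2_ge, s2_e) for one trait of a tidy trial table.

    ``table`` needs columns ``line, env, rep, trait, value``.  Balanced
    designs use the expected-mean-squares method of moments; unbalanced
    designs fall back to REML via a mixed model.  With a single
    environment (or ``include_ge=False``) the GxE component is
    inestimable and set to 0 with a flag.
    """
    sub = _trait_table(table, trait)
    n_lines = sub["line"].nunique()
    n_env = sub["env"].nunique()
    if n_lines < 2:
        raise ValueError("need >= 2 lines to separate genetic variance")
    flags = []
    if n_env < 2 and include_ge:
        include_ge = False
        flags.append("single environment: sigma2_ge set to 0")

    if _is_balanced(sub):
        vc = _fit_balanced(sub, include_ge)
    else:
        vc = _fit_reml(sub, include_ge)
    vc.flags.extend(flags)
    return vc


def _fit_balanced(sub: pd.DataFrame, include_ge: bool) -> VarianceComponents:
    n = sub["line"].nunique()
    E = sub["env"].nunique()
    R = len(sub) // (n * E)
    y = sub["value"].to_numpy()
    grand = y.mean()
    line_means = sub.groupby("line", observed=True)["value"].mean()
    ms_g = E * R * ((line_means - grand) ** 2).sum() / (n - 1)

    if include_ge and E > 1 and R > 1:
        cell = sub.groupby(["line", "env"], observed=True)["value"].mean().unstack()
        interaction = (cell
                       - cell.mean(axis=1).to_numpy()[:, None]
                       - cell.mean(axis=0).to_numpy()[None, :] + grand)
        ms_ge = R * (interaction ** 2).to_numpy().sum() / ((n - 1) * (E - 1))
        cell_long = sub.set_index(["line", "env"])["value"]
        resid = cell_long - cell.stack().reindex(cell_long.index)
        ms_e = (resid ** 2).sum() / (n * E * (R - 1))
        s2_e = ms_e
        s2_ge = (ms_ge - ms_e) / R
        s2_g = (ms_g - ms_ge) / (E * R)
    else:
        # two-level model: y = mu + env + g + e, m = E*R obs per line
        env_means = sub.groupby("env", observed=True)["value"].transform("mean")
        adj = y - (env_means.to_numpy() - grand)
        resid = adj - sub["line"].map(line_means).to_numpy()
        df_res = len(sub) - n - (E - 1)
        ms_e = (resid ** 2).sum() / df_res
        s2_e = ms_e
        s2_ge = 0.0
        s2_g = (ms_g - ms_e) / (E * R)
    return VarianceComponents(sigma2_g=float(s2_g), sigma2_ge=float(s2_ge),
                              sigma2_e=float(s2_e), n_env=E, n_rep=float(R),
                              n_lines=n, method="moments")


def _fit_reml(sub: pd.DataFrame, include_ge: bool) -> VarianceComponents:
    import statsmodels.formula.api as smf

    n = sub["line"].nunique()
    E = sub["env"].nunique()
    n_rep = len(sub) / (n * E)
    data = sub.rename(columns={"value": "y"}).copy()
    vc = {"ge": "0 + C(env)"} if (include_ge and E > 1) else None
    fixed = "y ~ C(env)" if E > 1 else "y ~ 1"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(fixed, data, groups="line", re_formula="1",
                            vc_formula=vc)
        res = model.fit(reml=True)
    s2_g = float(res.cov_re.iloc[0, 0])
    s2_ge = float(res.vcomp[0]) if vc else 0.0
    return VarianceComponents(sigma2_g=s2_g, sigma2_ge=s2_ge,
                              sigma2_e=float(res.scale), n_env=E,
                              n_rep=n_rep, n_lines=n, method="reml")


def heritability(components: VarianceComponents) -> float:
    """Entry-mean broad-sense heritability in [0, 1]."""
    c = components
    denom = c.sigma2_g + c.sigma2_ge / c.n_env + c.sigma2_e / (c.n_env * c.n_rep)
    if denom == 0:
        raise ValueError("all variance components are zero; H^2 undefined")
    return c.sigma2_g / denom


def compute_blups(table: pd.DataFrame, trait: str,
                  components: VarianceComponents | None = None) -> pd.Series:
    """Per-line BLUPs (deviations from the grand mean) for one trait.

    Line means are first adjusted for environment effects, then shrunk
    toward zero by lambda_i = s2_g / (s2_g + s2_ge/E_i + s2_e/n_i),
    where E_i and n_i are the environments and observations available
    for line *i* (for a balanced trial this is the textbook balanced
    shrinkage factor).  BLUPs of lines absent from the trait are NaN.
    """
    sub = _trait_table(table, trait)
    if components is None:
        components = fit_variance_components(table, trait)
    grand = sub["value"].mean()
    env_effect = sub.groupby("env", observed=True)["value"].transform("mean") - grand
    adj = sub["value"] - env_effect
    line_means = adj.groupby(sub["line"], observed=True).mean()
    n_i = sub.groupby("line", observed=True).size()
    e_i = sub.groupby("line", observed=True)["env"].nunique()

    s2g, s2ge, s2e = (components.sigma2_g, components.sigma2_ge,
                      components.sigma2_e)
    if s2g == 0:
        lam = pd.Series(0.0, index=line_means.index)
    else:
        lam = s2g / (s2g + s2ge / e_i + s2e / n_i)
    blup = lam * (line_means - grand)
    blup.name = trait
    return blup


def blup_table(table: pd.DataFrame, traits=None) -> pd.DataFrame:
    """Wide lines x traits table of BLUPs for every (or given) trait."""
    traits = traits if traits is not None else list(table["trait"].unique())
    return pd.concat([compute_blups(table, t) for t in traits], axis=1)


def trait_correlations(blups: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-complete Pearson correlations among trait BLUPs."""
    if len(blups) < 3:
        raise ValueError("need >= 3 lines for correlations")
    constant = [c for c in blups.columns if blups[c].nunique(dropna=True) <= 1]
    corr = blups.corr(method="pearson")
    for c in constant:
        corr.loc[c, :] = np.nan
        corr.loc[:, c] = np.nan
        corr.loc[c, c] = 1.0
    return corr
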