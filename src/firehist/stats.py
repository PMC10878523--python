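"""Fire effects on lidar-derived forest structure.

Joins footprint-level structure metrics (PAI, canopy cover, canopy
height) to the fire history, then runs the analysis battery:

* Kruskal-Wallis rank test of each metric across burn-count groups,
  implemented from the rank-sum formula with ties correction so it can be
  checked against an independent brute-force computation;
* Dunn's post-hoc pairwise test with Bonferroni correction, from pooled
  ranks with the same ties correction;
* linear mixed models ``metric ~ n_fires + n_months`` with crossed random
  intercepts for observation season (dry/wet) and management zone, fitted
  by REML through statsmodels;
* a directional recovery assessment labelling each fixed effect
  declining / flat / recovering.

The mixed models are fitted on burned footprints only by default, so the
months-since-fire covariate is defined for every row; unburned footprints
can be included (with n_months coded 0) via a switch.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .history import NEVER, FireHistoryMap
from .raster import index_to_ym
from .synthetic import DRY_SEASON_MONTHS

__all__ = [
    "MixedModelResult",
    "filter_and_attach",
    "kruskal_wallis",
    "dunn_posthoc",
    "fit_structure_model",
    "recovery_assessment",
]

RESPONSES = ("pai", "cc", "ch")


# ---------------------------------------------------------------------------
# join footprints to fire history
# ---------------------------------------------------------------------------

def filter_and_attach(footprints: pd.DataFrame, history: FireHistoryMap,
                      forest_mask: np.ndarray, zone_map: np.ndarray | None = None,
                      zone_names: tuple[str, ...] | None = None,
                      exclude_zones: tuple[str, ...] = ("peripheral",),
                      require_quality: bool = True) -> pd.DataFrame:
    """Quality/forest/zone filtering and burn-covariate attachment.

    Keeps footprints passing the quality flag, inside the forest base map
    and outside excluded zones; attaches ``n_fires`` and ``months_since``
    (sentinel -1 = never burned) relative to each footprint's acquisition
    month, counting only burns on or before it.
    """
    df = footprints.copy()
    H, W = forest_mask.shape
    if ((df["row"] < 0) | (df["row"] >= H) | (df["col"] < 0) | (df["col"] >= W)).any():
        raise ValueError("footprint outside the grid")
    keep = np.ones(len(df), dtype=bool)
    if require_quality and "quality_ok" in df:
        keep &= df["quality_ok"].to_numpy(dtype=bool)
    keep &= forest_mask[df["row"].to_numpy(), df["col"].to_numpy()]
    if zone_map is not None:
        zidx = zone_map[df["row"].to_numpy(), df["col"].to_numpy()]
        if zone_names is not None:
            znames = np.asarray(zone_names)[zidx]
            df["zone"] = znames
        keep &= ~np.isin(df["zone"].to_numpy(), list(exclude_zones))
    elif "zone" in df:
        keep &= ~df["zone"].isin(exclude_zones).to_numpy()
    df = df.loc[keep].reset_index(drop=True)

    nf = np.empty(len(df), dtype=int)
    msf = np.empty(len(df), dtype=int)
    for i, (r, c, m) in enumerate(zip(df["row"], df["col"], df["month_index"])):
        nf[i] = history.n_fires_at(int(r), int(c), int(m))
        msf[i] = history.months_since_at(int(r), int(c), int(m))
    df["n_fires"] = nf
    df["months_since"] = msf
    if "season" not in df:
        cal = df["month"] if "month" in df else [
            index_to_ym(int(m), (0, 1))[1] for m in df["month_index"]]
        df["season"] = np.where(np.isin(cal, list(DRY_SEASON_MONTHS)), "dry", "wet")
    return df


# ---------------------------------------------------------------------------
# rank tests (implemented from the formulas)
# ---------------------------------------------------------------------------

def _pooled_ranks(groups: list[np.ndarray]):
    values = np.concatenate(groups)
    n = len(values)
    ranks = sps.rankdata(values)
    # ties correction factor: 1 - sum(t^3 - t) / (N^3 - N)
    _, counts = np.unique(values, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    correction = 1.0 - tie_sum / (n**3 - n) if n > 1 else 1.0
    split = np.cumsum([len(g) for g in groups])[:-1]
    return np.split(ranks, split), n, correction, tie_sum


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (ties-corrected) and its chi-square p-value.

    ``groups`` is a sequence of 1-D samples, one per burn-count class.
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) > 0]
    if len(groups) < 2:
        raise ValueError("at least two non-empty groups required")
    group_ranks, n, correction, _ = _pooled_ranks(groups)
    h = 12.0 / (n * (n + 1)) * sum(
        r.sum()**2 / len(r) for r in group_ranks) - 3.0 * (n + 1)
    if correction > 0:
        h /= correction
    dof = len(groups) - 1
    p = float(sps.chi2.sf(h, dof))
    return float(h), p


def dunn_posthoc(groups: list, labels: list | None = None,
                 correction: str = "bonferroni") -> pd.DataFrame:
    """Dunn's pairwise z tests on the pooled ranking, Bonferroni-adjusted.

    Returns a tidy frame with one row per pair: z, raw p and adjusted p
    (raw p times the number of comparisons, capped at 1).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = list(range(len(groups)))
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty group")
    group_ranks, n, _, tie_sum = _pooled_ranks(groups)
    mean_ranks = [r.mean() for r in group_ranks]
    sizes = [len(g) for g in groups]
    var_base = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    pairs = list(itertools.combinations(range(len(groups)), 2))
    m = len(pairs)
    rows = []
    for i, j in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p = 2.0 * sps.norm.sf(abs(z))
        p_adj = min(1.0, p * m) if correction == "bonferroni" else p
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "z": float(z), "p": float(p), "p_adj": float(p_adj)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# linear mixed models
# ---------------------------------------------------------------------------

@dataclass
class MixedModelResult:
    """Fixed effects, random-effect variances, and fit diagnostics."""

    response: str
    coefficients: dict           # name -> {"estimate", "se", "p"}
    variance_components: dict    # grouping -> variance
    residual_variance: float
    n_obs: int
    converged: bool
    singular: bool
    notes: str = ""

    def coef(self, name: str) -> float:
        return self.coefficients[name]["estimate"]

    def validate(self) -> None:
        if any(v < 0 for v in self.variance_components.values()):
            raise AssertionError("negative variance component")


def fit_structure_model(table: pd.DataFrame, response: str,
                        include_unburned: bool = False,
                        reml: bool = True) -> MixedModelResult:
    """Mixed model: response ~ n_fires + n_months, random season and zone.

    By default only burned footprints enter (months-since-fire is then
    well-defined); with ``include_unburned`` the never-burned rows are
    included with n_months coded 0.  Season and zone are crossed random
    intercepts fitted as variance components; a singular fit (a variance
    component at zero or non-convergence) is reported, never hidden.
    """
    if response not in table.columns:
        raise KeyError(f"response {response!r} not in table")
    df = table.copy()
    if include_unburned:
        df["n_months"] = np.where(df["months_since"] == NEVER, 0, df["months_since"])
    else:
        df = df[df["months_since"] != NEVER].copy()
        df["n_months"] = df["months_since"]
    df = df.dropna(subset=[response, "n_fires", "n_months", "season", "zone"])
    for col in ("season", "zone"):
        if df[col].nunique() < 2:
            raise ValueError(f"random grouping {col!r} needs >= 2 levels")

    df["_g"] = 1  # single top-level group; crossed effects as variance comps
    vcf = {"zone": "0 + C(zone)", "season": "0 + C(season)"}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{response} ~ n_fires + n_months", data=df,
                            groups="_g", vc_formula=vcf, re_formula="0")
        fit = model.fit(reml=reml, method=["lbfgs", "powell"])
        coefs = {}
        for name in fit.fe_params.index:
            key = "intercept" if name == "Intercept" else name
            coefs[key] = {
                "estimate": float(fit.fe_params[name]),
                "se": float(fit.bse_fe[name]),
                "p": float(fit.pvalues[name]),
            }
    vcomp = {name: float(v) for name, v in zip(model.exog_vc.names, fit.vcomp)}
    singular = any(v <= 1e-10 for v in vcomp.values())
    result = MixedModelResult(
        response=response, coefficients=coefs, variance_components=vcomp,
        residual_variance=float(fit.scale), n_obs=int(fit.nobs),
        converged=bool(fit.converged), singular=singular,
        notes="singular fit: a variance component is ~0" if singular else "")
    result.validate()
    return result


def recovery_assessment(table: pd.DataFrame, alpha: float = 0.05,
                        responses: tuple[str, ...] = RESPONSES,
                        include_unburned: bool = False) -> pd.DataFrame:
    """Directional report on fire effects per structure metric.

    Labels the months-since-fire effect as ``recovering`` (positive,
    significant), ``declining`` (negative, significant) or ``flat``, and
    the burn-count effect likewise, from the mixed models.
    """
    rows = []
    for resp in responses:
        res = fit_structure_model(table, resp, include_unburned=include_unburned)

        def label(term):
            c = res.coefficients[term]
            if c["p"] < alpha:
                return "declining" if c["estimate"] < 0 else "recovering"
            return "flat"

        rows.append({
            "response": resp,
            "n_fires_effect": label("n_fires"),
            "n_fires_coef": res.coef("n_fires"),
            "n_fires_p": res.coefficients["n_fires"]["p"],
            "n_months_effect": label("n_months"),
            "n_months_coef": res.coef("n_months"),
            "n_months_p": res.coefficients["n_months"]["p"],
            "n_obs": res.n_obs,
            "converged": res.converged,
        })
    return pd.DataFrame(rows)
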