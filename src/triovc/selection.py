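"""Model comparison, variance decomposition and gene-environment correlation.

Comparison of the four nested specifications uses AIC with fixed effects
counted as estimated parameters (``AIC = -2ll + 2 * (df + 2)`` for an
intercept and a sex effect) and sequential likelihood-ratio tests with a
plain chi-square reference at the parameter-count difference.  The
variance decomposition splits the standardized components into the
direct share, the combined indirect parental share, the direct-indirect
covariance contribution and the residual; the gene-environment
correlation is the implied correlation between direct and combined
indirect effects,

    r_ge = (cov_om + cov_op) / sqrt(var_o * (var_m + var_p)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import InputError
from .model import COMPONENT_NAMES, NESTING_ORDER, VCFit, is_nested, standardize_fit

__all__ = [
    "aic",
    "lrt",
    "Decomposition",
    "decompose_variance",
    "model_table",
    "render_table",
    "decomposition_figure",
]

N_FIXED_DEFAULT = 2  # intercept + sex


def _neg2ll_df(fit) -> tuple[float, int]:
    if isinstance(fit, VCFit):
        return fit.neg2_loglik, fit.df
    neg2ll, df = fit
    return float(neg2ll), int(df)


def aic(fit, n_fixed: int = N_FIXED_DEFAULT) -> float:
    """Akaike information criterion, counting fixed effects as parameters.

    ``fit`` is either a :class:`VCFit` or a ``(neg2_loglik, df)`` pair
    (so printed fit statistics can be fed in directly).
    """
    neg2ll, df = _neg2ll_df(fit)
    return neg2ll + 2.0 * (df + n_fixed)


def lrt(nested, full) -> tuple[float, int, float]:
    """Likelihood-ratio test of a nested against a fuller specification.

    Returns ``(delta, df_diff, p)`` where ``delta`` is the difference in
    -2 log-likelihood (floored at zero) and ``p`` the upper-tail
    chi-square probability at the parameter-count difference.  Accepts
    :class:`VCFit` objects or ``(neg2_loglik, df)`` pairs.
    """
    if isinstance(nested, VCFit) and isinstance(full, VCFit):
        if not is_nested(nested.spec, full.spec):
            raise InputError(
                f"{nested.spec.name!r} is not nested within {full.spec.name!r}"
            )
    n2_nested, df_nested = _neg2ll_df(nested)
    n2_full, df_full = _neg2ll_df(full)
    df_diff = df_full - df_nested
    if df_diff <= 0:
        raise InputError("the full model must have more free parameters")
    delta = max(n2_nested - n2_full, 0.0)
    p = float(stats.chi2.sf(delta, df=df_diff)) if delta > 0 else 1.0
    return delta, df_diff, p


@dataclass
class Decomposition:
    """Standardized variance shares and the gene-environment correlation."""

    direct: float                  # var_o
    indirect: float                # var_m + var_p
    covariance: float              # cov_om + cov_op
    residual: float
    explained: float               # 1 - residual
    ge_correlation: float          # NaN when undefined
    se: dict | None = None

    def as_dict(self) -> dict:
        return {
            "direct": self.direct,
            "indirect": self.indirect,
            "covariance": self.covariance,
            "residual": self.residual,
            "explained": self.explained,
            "ge_correlation": self.ge_correlation,
        }


def _components_from(fit) -> tuple[pd.Series, np.ndarray | None]:
    if isinstance(fit, VCFit):
        if fit.standardized is None:
            fit = standardize_fit(fit)
        return fit.standardized.components, fit.standardized.cov
    comp = pd.Series(fit, dtype=float).reindex(COMPONENT_NAMES).fillna(0.0)
    return comp, None


def decompose_variance(fit) -> Decomposition:
    """Decompose a standardized fit (or a plain component mapping).

    Accepts a :class:`VCFit` (standardized on the fly when needed) or any
    mapping of the seven component names to standardized values, e.g. a
    published results row.  Delta-method SEs are attached when a
    component covariance is available.
    """
    comp, cov = _components_from(fit)
    direct = float(comp["var_o"])
    indirect = float(comp["var_m"] + comp["var_p"])
    covariance = float(comp["cov_om"] + comp["cov_op"])
    residual = float(comp["resid"])
    prod = direct * indirect
    ge = covariance / np.sqrt(prod) if prod > 0 else float("nan")

    se = None
    if cov is not None:
        idx = {name: i for i, name in enumerate(COMPONENT_NAMES)}
        grads = {
            "direct": _indicator(idx, ["var_o"]),
            "indirect": _indicator(idx, ["var_m", "var_p"]),
            "covariance": _indicator(idx, ["cov_om", "cov_op"]),
            "residual": _indicator(idx, ["resid"]),
            "explained": -_indicator(idx, ["resid"]),
        }
        if prod > 0:
            g = np.zeros(7)
            root = np.sqrt(prod)
            g[idx["cov_om"]] = g[idx["cov_op"]] = 1.0 / root
            g[idx["var_o"]] = -0.5 * covariance / (root * direct)
            g[idx["var_m"]] = g[idx["var_p"]] = -0.5 * covariance / (root * indirect)
            grads["ge_correlation"] = g
        se = {
            name: float(np.sqrt(max(g @ cov @ g, 0.0)))
            for name, g in grads.items()
        }
    return Decomposition(
        direct=direct,
        indirect=indirect,
        covariance=covariance,
        residual=residual,
        explained=1.0 - residual,
        ge_correlation=float(ge),
        se=se,
    )


def _indicator(idx: dict, names: list[str]) -> np.ndarray:
    g = np.zeros(7)
    for n in names:
        g[idx[n]] = 1.0
    return g


_ROW_ORDER = tuple(reversed(NESTING_ORDER))  # differential first


def model_table(fits, subscale: str | None = None) -> pd.DataFrame:
    """Comparison table for the fitted specifications of one phenotype.

    Rows are ordered from the most to the least elaborate specification;
    each row carries the standardized components, -2ll, AIC, df, the
    sequential LRT p-value against the next-larger specification, and a
    best-model flag on the lowest AIC.  Values are kept at full
    precision; use :func:`render_table` for display rounding.
    """
    if len(fits) < 2:
        raise InputError("model_table requires at least two fits")
    by_name = {}
    for f in fits:
        if f.spec.name in by_name:
            raise InputError(f"duplicate specification {f.spec.name!r}")
        by_name[f.spec.name] = f

    rows = []
    present = [n for n in _ROW_ORDER if n in by_name]
    aics = {n: aic(by_name[n]) for n in present}
    best = min(aics, key=aics.get)
    for name in present:
        fit = by_name[name]
        comp, _ = _components_from(fit)
        row = {"model": name, "subscale": subscale}
        row.update({c: comp[c] if fit.spec.expansion[i].any() else np.nan
                    for i, c in enumerate(COMPONENT_NAMES)})
        row["neg2_loglik"] = fit.neg2_loglik
        row["aic"] = aics[name]
        row["df"] = fit.df
        larger = _ROW_ORDER[_ROW_ORDER.index(name) - 1] if _ROW_ORDER.index(name) > 0 else None
        if larger is not None and larger in by_name:
            _, _, p = lrt(fit, by_name[larger])
            row["p_value"] = p
        else:
            row["p_value"] = np.nan
        row["best"] = name == best
        rows.append(row)
    table = pd.DataFrame(rows)
    if subscale is None:
        table = table.drop(columns=["subscale"])
    return table


def render_table(table: pd.DataFrame) -> pd.DataFrame:
    """Display rounding: 3 decimals for estimates, 2 for AIC and p-values."""
    out = table.copy()
    for c in COMPONENT_NAMES:
        if c in out:
            out[c] = out[c].round(3)
    for c in ("neg2_loglik", "aic", "p_value"):
        if c in out:
            out[c] = out[c].round(2)
    return out


def decomposition_figure(decompositions: dict, ax=None):
    """Stacked-bar variance decomposition, one bar per phenotype.

    ``decompositions`` maps labels to :class:`Decomposition` objects.
    Negative covariance contributions hang below zero.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(decompositions), 4))
    labels = list(decompositions)
    parts = ("direct", "indirect", "covariance", "residual")
    colors = {"direct": "#4c72b0", "indirect": "#dd8452",
              "covariance": "#55a868", "residual": "#c4c4c4"}
    x = np.arange(len(labels))
    pos = np.zeros(len(labels))
    neg = np.zeros(len(labels))
    for part in parts:
        vals = np.array([getattr(decompositions[l], part) for l in labels])
        bottoms = np.where(vals >= 0, pos, neg)
        ax.bar(x, vals, bottom=bottoms, label=part, color=colors[part])
        pos += np.where(vals >= 0, vals, 0)
        neg += np.where(vals < 0, vals, 0)
    ax.set_xticks(x, labels)
    ax.axhline(0, color="k", lw=0.8)
    ax.set_ylabel("share of phenotypic variance")
    ax.legend(frameon=False, fontsize=8)
    return ax
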