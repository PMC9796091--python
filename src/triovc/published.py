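"""Published fit statistics for the four externalizing subscales.

These are the reported standardized variance components and fit
statistics from the motivating trio study of maternally reported
externalizing symptoms (conduct, inattention, hyperactivity and
oppositional-defiant subscales at age 8, 9,675 genotyped
parent-offspring trios).  The raw cohort data are access-restricted, so
these summary numbers serve as worked-example inputs: the package's AIC,
likelihood-ratio and decomposition arithmetic reproduces every derived
quantity the original report prints from them.

Component keys follow :data:`triovc.model.COMPONENT_NAMES`; ``p_value``
holds the printed two-decimal string (``"<.01"`` for values below .01,
``None`` where no sequential test applies).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["PUBLISHED_FITS", "published_frame", "N_TRIOS_PUBLISHED"]

N_TRIOS_PUBLISHED = 9675

# subscale -> model -> record
PUBLISHED_FITS: dict[str, dict[str, dict]] = {
    "conduct": {
        "differential": {
            "components": {"var_o": 0.266, "var_m": 0.059, "var_p": 0.137,
                           "cov_om": -0.114, "cov_op": -0.173, "cov_mp": 0.090,
                           "resid": 0.824},
            "neg2_loglik": 27403.48, "aic": 27421.48, "df": 7, "p_value": None,
            "best": False,
        },
        "combined": {
            "components": {"var_o": 0.191, "var_m": 0.071, "var_p": 0.071,
                           "cov_om": -0.083, "cov_op": -0.083, "cov_mp": 0.071,
                           "resid": 0.831},
            "neg2_loglik": 27406.86, "aic": 27418.86, "df": 4, "p_value": ".34",
            "best": True,
        },
        "no_parental": {
            "components": {"var_o": 0.077, "resid": 0.923},
            "neg2_loglik": 27413.43, "aic": 27421.43, "df": 2, "p_value": ".04",
            "best": False,
        },
        "null": {
            "components": {"resid": 1.00},
            "neg2_loglik": 27417.56, "aic": 27423.56, "df": 1, "p_value": ".04",
            "best": False,
        },
    },
    "inattention": {
        "differential": {
            "components": {"var_o": 0.238, "var_m": 0.061, "var_p": 0.144,
                           "cov_om": -0.020, "cov_op": -0.107, "cov_mp": 0.062,
                           "resid": 0.685},
            "neg2_loglik": 27605.66, "aic": 27623.66, "df": 7, "p_value": None,
            "best": False,
        },
        "combined": {
            "components": {"var_o": 0.240, "var_m": 0.082, "var_p": 0.082,
                           "cov_om": -0.064, "cov_op": -0.064, "cov_mp": 0.082,
                           "resid": 0.726},
            "neg2_loglik": 27608.97, "aic": 27620.97, "df": 4, "p_value": ".35",
            "best": True,
        },
        "no_parental": {
            "components": {"var_o": 0.199, "resid": 0.801},
            "neg2_loglik": 27614.01, "aic": 27622.01, "df": 2, "p_value": ".08",
            "best": False,
        },
        "null": {
            "components": {"resid": 1.00},
            "neg2_loglik": 27641.47, "aic": 27647.47, "df": 1, "p_value": "<.01",
            "best": False,
        },
    },
    "hyperactivity": {
        "differential": {
            "components": {"var_o": 0.115, "var_m": 0.054, "var_p": 0.041,
                           "cov_om": 0.037, "cov_op": 0.025, "cov_mp": 0.029,
                           "resid": 0.728},
            "neg2_loglik": 27536.51, "aic": 27554.51, "df": 7, "p_value": None,
            "best": False,
        },
        "combined": {
            "components": {"var_o": 0.116, "var_m": 0.039, "var_p": 0.039,
                           "cov_om": 0.030, "cov_op": 0.030, "cov_mp": 0.039,
                           "resid": 0.746},
            "neg2_loglik": 27536.99, "aic": 27548.99, "df": 4, "p_value": ".92",
            "best": True,
        },
        "no_parental": {
            "components": {"var_o": 0.221, "resid": 0.779},
            "neg2_loglik": 27544.64, "aic": 27552.64, "df": 2, "p_value": ".02",
            "best": False,
        },
        "null": {
            "components": {"resid": 1.00},
            "neg2_loglik": 27579.26, "aic": 27585.26, "df": 1, "p_value": "<.01",
            "best": False,
        },
    },
    "oppositional": {
        "differential": {
            "components": {"var_o": 0.183, "var_m": 0.059, "var_p": 0.038,
                           "cov_om": -0.028, "cov_op": -0.069, "cov_mp": 0.035,
                           "resid": 0.818},
            "neg2_loglik": 27538.14, "aic": 27556.14, "df": 7, "p_value": None,
            "best": False,
        },
        "combined": {
            "components": {"var_o": 0.122, "var_m": 0.000, "var_p": 0.000,
                           "cov_om": 0.000, "cov_op": 0.000, "cov_mp": 0.000,
                           "resid": 0.878},
            "neg2_loglik": 27541.81, "aic": 27553.81, "df": 4, "p_value": ".30",
            "best": False,
        },
        "no_parental": {
            "components": {"var_o": 0.122, "resid": 0.878},
            "neg2_loglik": 27541.81, "aic": 27549.81, "df": 2, "p_value": "1.00",
            "best": True,
        },
        "null": {
            "components": {"resid": 1.00},
            "neg2_loglik": 27551.79, "aic": 27557.79, "df": 1, "p_value": "<.01",
            "best": False,
        },
    },
}

SUBSCALES = tuple(PUBLISHED_FITS)
MODEL_ORDER = ("differential", "combined", "no_parental", "null")


def published_frame() -> pd.DataFrame:
    """The published fit statistics as a tidy DataFrame."""
    rows = []
    for subscale, models in PUBLISHED_FITS.items():
        for model, rec in models.items():
            row = {"subscale": subscale, "model": model}
            row.update(rec["components"])
            row.update({k: rec[k] for k in ("neg2_loglik", "aic", "df",
                                            "p_value", "best")})
            rows.append(row)
    return pd.DataFrame(rows)
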