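"""Goodness-of-fit statistics for model validation.

The three measures standard in crop-model evaluation: the coefficient of
determination R2 (squared Pearson correlation), the Nash-Sutcliffe model
efficiency NSE = 1 - SS_err/SS_obs (1 perfect, 0 no better than the
observed mean), and the root mean square error in the input units.
"""

from __future__ import annotations

import numpy as np


class ZeroVarianceError(ValueError):
    """Observed series has no variance; NSE is undefined."""


def goodness_of_fit(predicted, observed) -> dict[str, float]:
    """R2, NSE and RMSE for paired predicted/observed series (n >= 2)."""
    pred = np.asarray(predicted, dtype=float)
    obs = np.asarray(observed, dtype=float)
    if pred.shape != obs.shape:
        raise ValueError("predicted and observed must have equal length")
    if pred.ndim != 1 or pred.size < 2:
        raise ValueError("need at least two paired values")
    ss_obs = float(np.sum((obs - obs.mean()) ** 2))
    if ss_obs == 0.0:
        raise ZeroVarianceError("observed series has zero variance; NSE undefined")
    ss_err = float(np.sum((obs - pred) ** 2))
    sd_pred = float(np.std(pred))
    r2 = float(np.corrcoef(pred, obs)[0, 1] ** 2) if sd_pred > 0 else 0.0
    return {
        "r2": r2,
        "nse": 1.0 - ss_err / ss_obs,
        "rmse": float(np.sqrt(ss_err / obs.size)),
    }
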