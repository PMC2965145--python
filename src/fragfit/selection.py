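"""Information-theoretic model selection: AICc, ranking, Akaike weights.

AICc = -2 logL + 2K + 2K(K+1)/(n-K-1); the model with the lowest AICc is
the most plausible, models within dAICc < 2 of it are considered equally
plausible, and Akaike weights express each model's relative likelihood
on a 0-1 scale.
"""

from __future__ import annotations

import warnings
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from .likelihood import FittedModel

__all__ = ["aicc", "akaike_weights", "build_selection_table", "format_selection_table"]

#: dAICc below which a model counts as equally plausible (strict inequality).
PLAUSIBILITY_DELTA = 2.0


def aicc(logL: float, K: int, n: int) -> float:
    """Akaike Information Criterion corrected for small samples."""
    if n <= K + 1:
        raise ValueError(
            f"AICc undefined for n={n}, K={K} (requires n > K + 1)"
        )
    return -2.0 * logL + 2.0 * K + 2.0 * K * (K + 1) / (n - K - 1)


def akaike_weights(aicc_values: Sequence[float]) -> np.ndarray:
    """Akaike weights w_i = exp(-d_i/2) / sum_j exp(-d_j/2), shift-stabilised."""
    a = np.asarray(aicc_values, dtype=float)
    if a.size == 0 or not np.all(np.isfinite(a)):
        raise ValueError("akaike_weights requires at least one finite AICc")
    delta = a - a.min()
    rel = np.exp(-delta / 2.0)
    return rel / rel.sum()


def build_selection_table(fitted_models: Sequence[FittedModel]) -> pd.DataFrame:
    """Rank converged fits by AICc.

    Returns a frame with columns ``model_id, K, logL, AICc, deltaAICc,
    weight, plausible`` sorted ascending by AICc (ties broken by model
    id).  Non-converged fits, and fits whose sample size is too small
    for the AICc correction, are excluded with a warning.
    """
    rows = []
    for fm in fitted_models:
        if not fm.converged:
            warnings.warn(
                f"model {fm.model.model_id} did not converge; excluded from selection"
            )
            continue
        try:
            a = aicc(fm.logL, fm.K, fm.n)
        except ValueError as exc:
            warnings.warn(f"model {fm.model.model_id} skipped: {exc}")
            continue
        rows.append(
            {"model_id": fm.model.model_id, "K": fm.K, "logL": fm.logL, "AICc": a}
        )
    if not rows:
        raise ValueError("no converged fits to rank")
    table = pd.DataFrame(rows)
    table["deltaAICc"] = table["AICc"] - table["AICc"].min()
    table["weight"] = akaike_weights(table["AICc"].to_numpy())
    table["plausible"] = table["deltaAICc"] < PLAUSIBILITY_DELTA
    table = table.sort_values(
        ["AICc", "model_id"], kind="mergesort", ignore_index=True
    )
    return table


def format_selection_table(table: pd.DataFrame) -> str:
    """Tab-separated report with columns M, K, logL, AICc, dAICc, Wi."""
    out = table.rename(
        columns={
            "model_id": "M",
            "deltaAICc": "dAICc",
            "weight": "Wi",
        }
    )[["M", "K", "logL", "AICc", "dAICc", "Wi"]]
    buf = StringIO()
    out.to_csv(buf, sep="\t", index=False, float_format="%.4f")
    return buf.getvalue()
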