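"""Accuracy metrics for digital vs manual stand counts.

R-squared follows the spreadsheet scatter-trendline convention: the squared
Pearson correlation between the two series.  That measures linear
association, not 1:1 agreement — a constant offset gives R^2 = 1 with a
nonzero MAE — so MAE and RMSE are reported alongside.  The 1:1-line variant
(1 - SSE/SST about identity) is available in the verbose report.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = ["AccuracyReport", "evaluate"]


@dataclass
class AccuracyReport:
    r_squared: float
    mae: float
    rmse: float
    n_plots: int
    r_squared_identity: float | None = None  # 1 - SSE/SST about the 1:1 line

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    def __str__(self) -> str:
        return (
            f"n={self.n_plots} plots  R^2={self.r_squared:.4f}  "
            f"MAE={self.mae:.2f}  RMSE={self.rmse:.2f}"
        )


def evaluate(pairs, verbose: bool = False) -> AccuracyReport:
    """Accuracy of digital counts against manual counts.

    Parameters
    ----------
    pairs:
        Sequence of ``(manual, digital)`` count pairs, or a 2-column array.

    Returns an :class:`AccuracyReport` with the squared Pearson correlation,
    mean absolute error and root-mean-square error.  Requires n >= 2 and
    nonzero variance in both series (a flat series has no defined
    correlation).
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("pairs must be (manual, digital) tuples")
    n = arr.shape[0]
    if n < 2:
        raise ValueError("need at least 2 plots to evaluate accuracy")
    manual, digital = arr[:, 0], arr[:, 1]
    if np.ptp(manual) == 0 or np.ptp(digital) == 0:
        raise ValueError("zero variance in counts: R^2 undefined")
    r = np.corrcoef(manual, digital)[0, 1]
    err = digital - manual
    report = AccuracyReport(
        r_squared=float(r * r),
        mae=float(np.abs(err).mean()),
        rmse=float(np.sqrt((err**2).mean())),
        n_plots=int(n),
    )
    if verbose:
        sst = float(((manual - manual.mean()) ** 2).sum())
        report.r_squared_identity = float(1.0 - (err**2).sum() / sst)
    return report


def scatter_plot(pairs, path: str | Path, title: str = "") -> Path:
    """Digital-vs-manual scatter with the 1:1 line (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    arr = np.asarray(list(pairs), dtype=float)
    rep = evaluate(arr)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(arr[:, 0], arr[:, 1], s=12, alpha=0.6)
    lim = [0, float(arr.max()) * 1.05]
    ax.plot(lim, lim, "r-", lw=1, label="1:1")
    ax.set_xlim(lim), ax.set_ylim(lim)
    ax.set_xlabel("manual count"), ax.set_ylabel("digital count")
    ax.set_title(title or str(rep))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
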