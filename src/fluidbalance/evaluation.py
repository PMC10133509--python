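"""Error metrics and cohort-level summaries of CFB predictions.

Window-level errors are measured two ways, both in liters:

* ``rmse_last_30min`` — the RMSE over the last 30 minutes (31 inclusive
  samples) before each prediction horizon, tracking how the error grows
  with horizon (8, 12, 16, 20, 24 h);
* ``endpoint_error`` — the signed predicted-minus-actual difference at the
  horizon itself, binned into clinically chosen tolerance bands (±0.5,
  ±1.0, ±1.5, ±2.0 L; 2 L being the upper limit of tolerable error).

Cohort aggregation first averages window RMSEs within each patient
("aggregated RMSE"), then combines patients with weights proportional to
their window counts, so the weighted mean equals the pooled mean over
windows while per-patient values remain inspectable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "HORIZONS_H",
    "BIN_EDGES_L",
    "rmse_last_30min",
    "endpoint_error",
    "bin_errors",
    "aggregate_patient_rmse",
    "weighted_mean_matrix",
    "summarize_results",
]

HORIZONS_H = (8, 12, 16, 20, 24)
BIN_EDGES_L = (0.5, 1.0, 1.5, 2.0)


def _horizon_index(series_len: int, horizon_h: float) -> int:
    idx = int(round(horizon_h * 60))
    if idx > series_len - 1:
        raise ValueError(f"series too short for a {horizon_h} h horizon")
    return idx


def rmse_last_30min(pred, actual, horizon_h: float) -> float:
    """RMSE over the 31 samples at minutes [60*h - 30, 60*h] inclusive."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if len(pred) != len(actual):
        raise ValueError("predicted and actual series lengths differ")
    idx = _horizon_index(len(pred), horizon_h)
    lo = max(idx - 30, 0)
    d = pred[lo : idx + 1] - actual[lo : idx + 1]
    return float(np.sqrt(np.mean(d * d)))


def endpoint_error(pred, actual, horizon_h: float) -> float:
    """Signed error pred[60*h] - actual[60*h] in liters."""
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if len(pred) != len(actual):
        raise ValueError("predicted and actual series lengths differ")
    idx = _horizon_index(len(pred), horizon_h)
    return float(pred[idx] - actual[idx])


def bin_errors(errors, edges: tuple[float, ...] = BIN_EDGES_L) -> dict[str, dict[str, float]]:
    """Percentages of signed errors within symmetric tolerance bands.

    Returns both cumulative bands (|e| <= 0.5, <= 1.0, ... plus "> 2.0")
    and disjoint shells (|e| in (0.5, 1.0], ...).  Percentages are of the
    total number of errors and each family sums to 100 (shells) while the
    cumulative family is nondecreasing.
    """
    errors = np.asarray(list(errors), dtype=float)
    if errors.size == 0:
        raise ValueError("no errors to bin")
    if not np.all(np.isfinite(errors)):
        raise ValueError("non-finite error values (exclude diverged windows first)")
    abs_e = np.abs(errors)
    n = errors.size
    cumulative = {f"<={e:g}": float(100.0 * np.mean(abs_e <= e)) for e in edges}
    cumulative[f">{edges[-1]:g}"] = float(100.0 * np.mean(abs_e > edges[-1]))
    shell = {}
    prev = 0.0
    for e in edges:
        shell[f"({prev:g},{e:g}]"] = float(100.0 * np.mean((abs_e > prev) & (abs_e <= e)))
        prev = e
    shell[f">{edges[-1]:g}"] = cumulative[f">{edges[-1]:g}"]
    # the innermost shell includes zero
    shell[f"(0,{edges[0]:g}]"] = cumulative[f"<={edges[0]:g}"]
    return {"cumulative": cumulative, "shell": shell}


def aggregate_patient_rmse(results_df: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mean window RMSE per (estimation time, horizon).

    Expects the long window table from ``results_to_frame``; diverged
    windows are dropped.  Returns columns patient_id, estimation_h,
    horizon_h, rmse_l, n_windows.
    """
    df = results_df[~results_df["diverged"]]
    long = df.melt(
        id_vars=["patient_id", "estimation_h"],
        value_vars=[f"rmse_{h}h" for h in HORIZONS_H],
        var_name="horizon",
        value_name="rmse_l",
    )
    long["horizon_h"] = long["horizon"].str.extract(r"rmse_(\d+)h").astype(int)
    out = (
        long.groupby(["patient_id", "estimation_h", "horizon_h"])["rmse_l"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "rmse_l", "size": "n_windows"})
    )
    return out


def weighted_mean_matrix(per_patient: pd.DataFrame) -> pd.DataFrame:
    """Cohort weighted mean of per-patient aggregated RMSE.

    Weights are each patient's window count for the combination, so the
    result equals the pooled mean over windows.  A plain (unweighted)
    patient mean is emitted alongside.  Cells with no valid windows are
    absent rather than zero.
    """
    def _agg(g: pd.DataFrame) -> pd.Series:
        w = g["n_windows"].to_numpy(dtype=float)
        v = g["rmse_l"].to_numpy(dtype=float)
        return pd.Series(
            {
                "weighted_mean_l": float(np.sum(w * v) / np.sum(w)),
                "pooled_mean_l": float(np.sum(w * v) / np.sum(w)),
                "patient_mean_l": float(np.mean(v)),
                "n": int(np.sum(w)),
                "n_patients": int(len(g)),
            }
        )

    return (
        per_patient.groupby(["estimation_h", "horizon_h"])
        .apply(_agg, include_groups=False)
        .reset_index()
    )


def summarize_results(results_df: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the two cohort summary tables from the window table.

    Returns ``(rmse_summary, bin_summary)``: the weighted-mean aggregated
    RMSE matrix in long format, and endpoint-error band percentages per
    (estimation time, horizon).
    """
    per_patient = aggregate_patient_rmse(results_df)
    rmse_summary = weighted_mean_matrix(per_patient)

    df = results_df[~results_df["diverged"]]
    rows = []
    for est_h, g in df.groupby("estimation_h"):
        for h in HORIZONS_H:
            errs = g[f"err_{h}h"].to_numpy(dtype=float)
            errs = errs[np.isfinite(errs)]
            if errs.size == 0:
                continue
            bins = bin_errors(errs)
            for bin_name, pct in bins["cumulative"].items():
                rows.append(
                    {
                        "estimation_h": est_h,
                        "horizon_h": h,
                        "bin": bin_name,
                        "percent": pct,
                        "n": errs.size,
                    }
                )
    return rmse_summary, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# plots (summary figures; headless-safe)


def plot_rmse_heatmap(rmse_summary: pd.DataFrame, path=None):
    """Weighted mean aggregated RMSE per (estimation, horizon)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    mat = rmse_summary.pivot(index="estimation_h", columns="horizon_h", values="weighted_mean_l")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(mat.to_numpy(), cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(mat.columns)), [f"{h} h" for h in mat.columns])
    ax.set_yticks(range(len(mat.index)), [f"{e} h" for e in mat.index])
    ax.set_xlabel("prediction time")
    ax.set_ylabel("estimation time")
    fig.colorbar(im, ax=ax, label="weighted mean RMSE (L)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_error_bands(bin_summary: pd.DataFrame, path=None):
    """Stacked bars of endpoint-error tolerance bands per combination."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est_times = sorted(bin_summary["estimation_h"].unique())
    fig, axes = plt.subplots(
        1, len(est_times), figsize=(3 * len(est_times), 4), sharey=True, squeeze=False
    )
    band_order = [f"<={e:g}" for e in BIN_EDGES_L] + [f">{BIN_EDGES_L[-1]:g}"]
    for ax, est in zip(axes[0], est_times):
        sub = bin_summary[bin_summary["estimation_h"] == est]
        horizons = sorted(sub["horizon_h"].unique())
        bottom = np.zeros(len(horizons))
        prev = np.zeros(len(horizons))
        for band in band_order:
            vals = np.array(
                [
                    sub[(sub["horizon_h"] == h) & (sub["bin"] == band)]["percent"].sum()
                    for h in horizons
                ]
            )
            shell = vals - prev if not band.startswith(">") else vals
            ax.bar([str(h) for h in horizons], shell, bottom=bottom, label=band)
            bottom += shell
            if not band.startswith(">"):
                prev = vals
        ax.set_title(f"estimation {est} h")
        ax.set_xlabel("prediction time (h)")
    axes[0][0].set_ylabel("% of predictions")
    axes[0][-1].legend(title="|error| band (L)", fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_rmse_distributions(per_patient: pd.DataFrame, path=None):
    """Violin plots of per-patient aggregated RMSE per combination."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    est_times = sorted(per_patient["estimation_h"].unique())
    fig, axes = plt.subplots(
        1, len(est_times), figsize=(3 * len(est_times), 4), sharey=True, squeeze=False
    )
    for ax, est in zip(axes[0], est_times):
        sub = per_patient[per_patient["estimation_h"] == est]
        horizons = sorted(sub["horizon_h"].unique())
        data = [sub[sub["horizon_h"] == h]["rmse_l"].to_numpy() for h in horizons]
        ax.violinplot(data, showmedians=True)
        ax.set_xticks(range(1, len(horizons) + 1), [str(h) for h in horizons])
        ax.set_title(f"estimation {est} h")
        ax.set_xlabel("prediction time (h)")
    axes[0][0].set_ylabel("aggregated RMSE (L)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
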