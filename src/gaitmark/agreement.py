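"""Method-comparison statistics against the reference system.

For each gait marker and each candidate modality, the paired per-trial
values (reference vs. candidate) are summarized with

* mean absolute error (MAE, mean +- SD of |test - ref|) and its
  percentage relative to the reference (MAEP),
* the Pearson correlation r with a two-sided p-value, and
* Bland-Altman bias and 95% limits of agreement (bias +- 1.96 SD of the
  differences; the 1.96 multiplier is fixed, not t-based).

Pairing is at the subject-trial level (each subject contributes one mean
per marker per trial), the granularity at which such comparisons are
conventionally published; per-stride pairing can be built by passing
per-stride values instead.  p-values are reported uncorrected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import AgreementResult, PairedMarkerSample


def mae(sample: PairedMarkerSample) -> tuple[float, float]:
    """Mean and sample SD (ddof=1) of the absolute paired differences."""
    d = np.abs(sample.test_values - sample.ref_values)
    return float(d.mean()), float(d.std(ddof=1))


def maep(sample: PairedMarkerSample) -> float:
    """Mean absolute error percentage: mean of 100*|test-ref|/|ref|."""
    if np.any(sample.ref_values == 0):
        raise ValueError("MAEP undefined when a reference value is zero")
    return float(
        np.mean(100.0 * np.abs(sample.test_values - sample.ref_values)
                / np.abs(sample.ref_values))
    )


def pearson(sample: PairedMarkerSample) -> tuple[float, float]:
    """Pearson r with a two-sided p from the t transform (n-2 df)."""
    if sample.n < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.std(sample.ref_values) == 0 or np.std(sample.test_values) == 0:
        raise ValueError("zero variance: r undefined")
    r, p = stats.pearsonr(sample.test_values, sample.ref_values)
    return float(r), float(p)


def bland_altman(sample: PairedMarkerSample) -> dict:
    """Bias, 95% limits of agreement and the per-point means/differences."""
    diffs = sample.test_values - sample.ref_values
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1)) if sample.n > 1 else 0.0
    return {
        "bias": bias,
        "loa_low": bias - 1.96 * sd,
        "loa_high": bias + 1.96 * sd,
        "means": (sample.test_values + sample.ref_values) / 2.0,
        "diffs": diffs,
    }


def compare(sample: PairedMarkerSample) -> AgreementResult:
    """All agreement statistics for one marker/modality pair."""
    m, s = mae(sample)
    try:
        mp = maep(sample)
    except ValueError:
        mp = None
    try:
        r, p = pearson(sample)
    except ValueError:
        r = p = None
    ba = bland_altman(sample)
    return AgreementResult(
        marker=sample.marker, units=sample.units, mae_mean=m, mae_sd=s,
        maep=mp, r=r, p_value=p, bias=ba["bias"],
        loa_low=ba["loa_low"], loa_high=ba["loa_high"],
    )


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Per-task agreement tables across markers and modalities."""

    task: str
    results: dict[tuple[str, str], AgreementResult] = field(default_factory=dict)
    samples: dict[tuple[str, str], PairedMarkerSample] = field(default_factory=dict)

    def add(self, modality: str, sample: PairedMarkerSample) -> None:
        self.samples[(sample.marker, modality)] = sample
        self.results[(sample.marker, modality)] = compare(sample)

    def modalities(self) -> list[str]:
        return sorted({m for _, m in self.results})

    def markers(self) -> list[str]:
        seen: list[str] = []
        for mk, _ in self.results:
            if mk not in seen:
                seen.append(mk)
        return seen

    def summary_frame(self):
        """Table-shaped frame: marker x modality means, SDs and MAE."""
        import pandas as pd

        rows = []
        for (mk, mod), res in self.results.items():
            sample = self.samples[(mk, mod)]
            rows.append({
                "marker": mk, "units": res.units, "modality": mod,
                "ref_mean": sample.ref_values.mean(),
                "ref_sd": sample.ref_values.std(ddof=1),
                "test_mean": sample.test_values.mean(),
                "test_sd": sample.test_values.std(ddof=1),
                "mae_mean": res.mae_mean, "mae_sd": res.mae_sd,
                "maep": res.maep,
            })
        return pd.DataFrame(rows)

    def correlation_frame(self):
        """Table-shaped frame: marker x modality r and p."""
        import pandas as pd

        rows = [
            {"marker": mk, "modality": mod, "r": res.r, "p_value": res.p_value}
            for (mk, mod), res in self.results.items()
        ]
        return pd.DataFrame(rows)


def bland_altman_plot(sample: PairedMarkerSample, ax=None, title: str | None = None):
    """Difference-vs-mean plot with bias and 95% limits of agreement."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ba = bland_altman(sample)
    ax.scatter(ba["means"], ba["diffs"], s=14, alpha=0.8)
    ax.axhline(ba["bias"], color="red", ls="--", label=f"bias {ba['bias']:.3g}")
    for y in (ba["loa_low"], ba["loa_high"]):
        ax.axhline(y, color="green", ls="--")
    ax.set_xlabel(f"mean of methods ({sample.units})")
    ax.set_ylabel(f"difference ({sample.units})")
    ax.set_title(title or sample.marker)
    ax.legend(fontsize=7)
    return ax


def r_vs_maep_plot(report: AgreementReport, ax=None,
                   r_threshold: float = 0.6, maep_threshold: float = 10.0):
    """Correlation-versus-MAEP scatter with acceptability thresholds."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4.5, 3.5))
    colors = {"foot_imu": "tab:blue", "lumbar_imu": "tab:orange", "kinect": "tab:green"}
    for (mk, mod), res in report.results.items():
        if res.r is None or res.maep is None:
            continue
        ax.scatter(res.maep, res.r, color=colors.get(mod, "gray"), label=mod, s=20)
        ax.annotate(mk, (res.maep, res.r), fontsize=5, alpha=0.6)
    ax.axhline(r_threshold, ls="--", color="k", lw=0.8)
    ax.axvline(maep_threshold, ls="--", color="k", lw=0.8)
    ax.set_xlabel("MAEP (%)")
    ax.set_ylabel("Pearson r")
    handles, labels = ax.get_legend_handles_labels()
    uniq = dict(zip(labels, handles))
    ax.legend(uniq.values(), uniq.keys(), fontsize=7)
    ax.set_title(report.task)
    return ax


def build_report(
    report: AgreementReport,
    out_dir,
    make_plots: bool = True,
) -> list[str]:
    """Write the summary/correlation CSVs and the plot files.

    Returns the list of written paths.  Marker/modality pairs whose r is
    undefined (zero variance) appear in the CSVs with empty r cells.
    """
    import pathlib

    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[str] = []
    f1 = out / f"summary_{report.task}.csv"
    report.summary_frame().to_csv(f1, index=False)
    written.append(str(f1))
    f2 = out / f"correlation_{report.task}.csv"
    report.correlation_frame().to_csv(f2, index=False)
    written.append(str(f2))
    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for (mk, mod), sample in report.samples.items():
            ax = bland_altman_plot(sample, title=f"{mk} - {mod} ({report.task})")
            f = out / f"bland_altman_{report.task}_{mk}_{mod}.png"
            ax.figure.savefig(f, dpi=100, bbox_inches="tight")
            plt.close(ax.figure)
            written.append(str(f))
        ax = r_vs_maep_plot(report)
        f = out / f"r_vs_maep_{report.task}.png"
        ax.figure.savefig(f, dpi=100, bbox_inches="tight")
        plt.close(ax.figure)
        written.append(str(f))
    return written
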