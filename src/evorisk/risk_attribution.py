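"""Median-split hazard ratios on held-out risk scores and the log-HR
fraction metrics attributing progression risk to feature classes.

Convention note: the hazard-ratio exponent is taken as the *difference of
per-group mean* risk scores (malignant minus benign).  With an exact median
split, group sums and means differ by a count factor that cancels in the
fraction ratios; means keep odd-sized cohorts well-defined.  Samples with a
risk score exactly at the median go to the benign group ("larger than the
median" is strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .survival_core import KMCurve, LogrankResult, km_curve, logrank


class UninformativeSplitError(ValueError):
    pass


@dataclass
class RiskSplit:
    """Median split of scored samples into predicted-malignant / benign."""

    malignant: np.ndarray  # boolean mask
    benign: np.ndarray
    threshold: float


@dataclass
class FractionEstimate:
    """Log-HR fractions of risk attributable to feature classes."""

    fraction_evolutionary: float
    fraction_genomic: float
    hr_by_run: dict  # run label -> per-replicate HR array
    mean_hr: dict
    sd_hr: dict


def median_split(eta) -> RiskSplit:
    """Split at the median risk score; strictly-greater scores are malignant."""
    eta = np.asarray(eta, dtype=float)
    if len(eta) < 2:
        raise ValueError("need at least two scored samples")
    thr = float(np.median(eta))
    malignant = eta > thr
    return RiskSplit(malignant=malignant, benign=~malignant, threshold=thr)


def hazard_ratio(eta, flag_uninformative: bool = False) -> float:
    """Median-split hazard ratio: ``exp(mean eta_malignant - mean eta_benign)``.

    Always >= 1 by construction.  A constant risk vector yields HR = 1; with
    ``flag_uninformative`` that case raises instead.
    """
    eta = np.asarray(eta, dtype=float)
    split = median_split(eta)
    if not split.malignant.any():
        if flag_uninformative:
            raise UninformativeSplitError("all risk scores identical: HR = 1, uninformative")
        return 1.0
    log_hr = float(eta[split.malignant].mean() - eta[split.benign].mean())
    return float(np.exp(log_hr))


def replicate_hazard_ratios(result) -> np.ndarray:
    """One pooled-held-out HR per replicate of a :class:`TwoLoopResult`."""
    reps = sorted(result.predictions["replicate"].unique())
    return np.asarray([hazard_ratio(result.pooled_eta(r).to_numpy()) for r in reps])


def fraction_metrics(
    evolutionary_run,
    genomic_run,
    full_run,
) -> FractionEstimate:
    """Fractions of explainable risk per feature class.

    Takes the two-loop results of the three feature-set runs (evolutionary
    only, evolutionary+driver, full = evolutionary+driver+clinical), which
    must have scored the same cohort with the same outer splits.  Per
    replicate the pooled held-out scores give one HR per run; HRs are
    averaged arithmetically over replicates and the fractions are ratios of
    the log mean-HRs:

    ``fraction(evolutionary) = log HR(evo) / log HR(full)`` and
    ``fraction(genomic) = log HR(evo+driver) / log HR(full)``.
    """
    runs = {"evolutionary": evolutionary_run, "genomic": genomic_run, "full": full_run}
    hr_by_run = {label: replicate_hazard_ratios(run) for label, run in runs.items()}
    mean_hr = {label: float(np.mean(v)) for label, v in hr_by_run.items()}
    sd_hr = {
        label: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for label, v in hr_by_run.items()
    }
    log_full = np.log(mean_hr["full"])
    if log_full == 0.0:
        raise UninformativeSplitError("full-model log HR is zero: fractions undefined")
    return FractionEstimate(
        fraction_evolutionary=float(np.log(mean_hr["evolutionary"]) / log_full),
        fraction_genomic=float(np.log(mean_hr["genomic"]) / log_full),
        hr_by_run=hr_by_run,
        mean_hr=mean_hr,
        sd_hr=sd_hr,
    )


@dataclass
class StratificationReport:
    split: RiskSplit
    km_malignant: KMCurve
    km_benign: KMCurve
    logrank: LogrankResult


def stratification_report(eta, y, delta, plot_path=None) -> StratificationReport:
    """KM curves for the median-split groups plus the logrank test.

    Optionally renders the two curves to ``plot_path`` (matplotlib, Agg)."""
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    delta = np.asarray(delta, dtype=int)
    split = median_split(eta)
    if not split.malignant.any() or not split.benign.any():
        raise UninformativeSplitError("median split left one group empty")
    km_m = km_curve(y[split.malignant], delta[split.malignant])
    km_b = km_curve(y[split.benign], delta[split.benign])
    lr = logrank(y[split.malignant], delta[split.malignant], y[split.benign], delta[split.benign])
    if plot_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(5, 4))
        for curve, label in ((km_m, "predicted malignant"), (km_b, "predicted benign")):
            t = np.concatenate([[0.0], np.repeat(curve.times, 2)])
            s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)[:-1]]) if len(
                curve.times
            ) else np.asarray([1.0])
            ax.plot(t, s[: len(t)], drawstyle="steps-post", label=label)
        ax.set_xlabel("time")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.02)
        ax.legend()
        ax.set_title(f"logrank p = {lr.p:.2e}")
        fig.tight_layout()
        fig.savefig(plot_path, dpi=150)
        plt.close(fig)
    return StratificationReport(split=split, km_malignant=km_m, km_benign=km_b, logrank=lr)
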