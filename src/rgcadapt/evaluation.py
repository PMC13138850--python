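"""Performance and reliability metrics.

Model quality is the Pearson correlation between the predicted rate and the
across-trial mean response on the held-out repeating segment.  Response
reliability is the correlation between averaged odd- and even-numbered
repeating trials.  In-domain (ID) vs out-of-domain (OOD) performance is
compared per cell type with a two-sided Wilcoxon signed-rank test on paired
differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ln_models import N_LAGS, predict_rate
from .synthetic_data import SpikeResponse, Stimulus

__all__ = [
    "CellEvaluation",
    "correlation",
    "odd_even_reliability",
    "compare_id_ood",
    "trial_averaged_response",
    "held_out_correlation",
]


@dataclass
class CellEvaluation:
    """Per-cell evaluation record: matched-domain and adapted correlations."""

    cell_id: str
    cell_type: str
    ensemble: str
    cc_id: float
    cc_ood: float
    n_test_bins: int = 0


def correlation(pred, trial_avg) -> float:
    """Sample Pearson correlation between a prediction and a trial-averaged
    response trace.

    Returns NaN (an undefined, to-be-excluded value) when either trace is
    constant.
    """
    pred = np.asarray(pred, dtype=float)
    trial_avg = np.asarray(trial_avg, dtype=float)
    if pred.shape != trial_avg.shape or pred.ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    if pred.size < 2:
        raise ValueError("need at least 2 bins")
    if np.ptp(pred) == 0 or np.ptp(trial_avg) == 0:
        return float("nan")
    return float(np.corrcoef(pred, trial_avg)[0, 1])


def repeating_counts(stimulus: Stimulus, response: SpikeResponse) -> np.ndarray:
    """(n_trials, n_rep_bins) spike counts over the repeating segments."""
    rows = []
    for tr, c in zip(stimulus.trials, response.counts):
        lo = tr.rep[0] - tr.nonrep[0]
        hi = tr.rep[1] - tr.nonrep[0]
        if hi > lo:
            rows.append(np.asarray(c[lo:hi], dtype=float))
    if not rows:
        raise ValueError("stimulus has no repeating segments")
    return np.stack(rows)


def trial_averaged_response(stimulus: Stimulus, response: SpikeResponse) -> np.ndarray:
    """Across-trial mean spike count on the repeating segment, valid bins only
    (the first ``N_LAGS - 1`` bins are dropped to match prediction support)."""
    return repeating_counts(stimulus, response).mean(axis=0)[N_LAGS - 1 :]


def held_out_correlation(params, stimulus: Stimulus, response: SpikeResponse) -> float:
    """Held-out test correlation: model prediction on the repeating sequence
    vs the trial-averaged response."""
    cropped = stimulus.crop(params.crop_center)
    tr = stimulus.trials[0]
    if tr.rep[1] <= tr.rep[0]:
        raise ValueError("stimulus has no repeating segment")
    pred = predict_rate(params, cropped[tr.rep[0] : tr.rep[1]])
    return correlation(pred, trial_averaged_response(stimulus, response))


def odd_even_reliability(stimulus: Stimulus, response: SpikeResponse) -> float:
    """Correlation between the mean responses of odd- and even-numbered
    repeating trials (1-based numbering: trials 1, 3, ... vs 2, 4, ...)."""
    counts = repeating_counts(stimulus, response)
    if counts.shape[0] < 2:
        raise ValueError("need at least 2 repeating trials")
    odd = counts[0::2].mean(axis=0)
    even = counts[1::2].mean(axis=0)
    return correlation(odd, even)


def compare_id_ood(evals: list[CellEvaluation]):
    """Per-cell-type ID vs OOD summary with paired Wilcoxon tests.

    Returns ``(summary, tests)``: a DataFrame with mean +- SD of the ID and
    OOD correlations and the mean paired difference per group, and a dict of
    per-group two-sided Wilcoxon signed-rank results.  Cells with an
    undefined correlation are dropped pairwise, with the dropped count
    reported; groups with fewer than 5 valid pairs are flagged underpowered.
    """
    df = pd.DataFrame(
        [
            {
                "cell_id": e.cell_id,
                "cell_type": e.cell_type,
                "ensemble": e.ensemble,
                "cc_id": e.cc_id,
                "cc_ood": e.cc_ood,
            }
            for e in evals
        ]
    )
    rows = []
    tests = {}
    for (ctype, ens), grp in df.groupby(["cell_type", "ensemble"]):
        valid = grp.dropna(subset=["cc_id", "cc_ood"])
        n_dropped = len(grp) - len(valid)
        diffs = (valid["cc_id"] - valid["cc_ood"]).to_numpy()
        entry = {
            "cell_type": ctype,
            "ensemble": ens,
            "n": len(valid),
            "n_dropped": n_dropped,
            "cc_id_mean": valid["cc_id"].mean(),
            "cc_id_sd": valid["cc_id"].std(),
            "cc_ood_mean": valid["cc_ood"].mean(),
            "cc_ood_sd": valid["cc_ood"].std(),
            "mean_diff": diffs.mean() if len(diffs) else float("nan"),
        }
        test = {"n": len(valid), "underpowered": len(valid) < 5}
        if len(diffs) and np.any(diffs != 0):
            res = stats.wilcoxon(diffs, alternative="two-sided")
            test.update(statistic=float(res.statistic), p_value=float(res.pvalue))
        else:
            # all differences zero (or no pairs): test sits at its null center
            test.update(statistic=float("nan"), p_value=1.0)
        rows.append(entry)
        tests[(ctype, ens)] = test
    return pd.DataFrame(rows), tests
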