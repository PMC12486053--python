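"""Cross-validated evaluation: decoding metrics, eigenvalue recovery, forecasts."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

__all__ = ["metric_cc", "metric_r2", "eigenvalue_error", "forecast_curve",
           "cross_validate", "EvalReport", "plot_forecast_curves"]


def plot_forecast_curves(curves: dict, path, metric: str = "behavior_cc"):
    """Save a metric-vs-horizon figure for one or more models.

    ``curves`` maps a label to a :func:`forecast_curve` result.  Requires
    matplotlib (the ``plot`` extra).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for label, c in curves.items():
        ax.plot(c["horizon"], c[metric], marker="o", label=label)
    ax.set_xlabel("steps ahead (m)")
    ax.set_ylabel(metric.replace("_", " "))
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _channel_metrics(pred, truth, fn):
    pred = np.atleast_2d(np.asarray(pred, float).T).T
    truth = np.atleast_2d(np.asarray(truth, float).T).T
    if pred.shape != truth.shape:
        raise ValueError("pred and truth must have identical shapes")
    if truth.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    keep = truth.std(axis=0) > 1e-12
    if not np.any(keep):
        raise ValueError("all channels have zero variance; metric undefined")
    if not np.all(keep):
        warnings.warn(f"excluding zero-variance channels "
                      f"{np.where(~keep)[0].tolist()} from the metric")
    vals = [fn(pred[:, j], truth[:, j]) for j in np.where(keep)[0]]
    return float(np.mean(vals))


def metric_cc(pred, truth) -> float:
    """Pearson correlation per channel, averaged across channels."""
    def _cc(p, t):
        ps, ts = p.std(), t.std()
        if ps < 1e-12:
            return 0.0
        return float(np.corrcoef(p, t)[0, 1])
    return _channel_metrics(pred, truth, _cc)


def metric_r2(pred, truth) -> float:
    """Coefficient of determination per channel, averaged (can be negative)."""
    def _r2(p, t):
        sse = np.sum((t - p) ** 2)
        sst = np.sum((t - t.mean()) ** 2)
        return float(1.0 - sse / sst)
    return _channel_metrics(pred, truth, _r2)


def eigenvalue_error(true_eigs, learned_eigs) -> float:
    """Normalised mean distance between matched eigenvalue sets.

    Matches the two sets one-to-one by minimising total complex-modulus
    distance (optimal assignment), then reports the mean matched distance
    divided by the mean modulus of the true set.  Invariant to ordering.
    """
    t = np.asarray(true_eigs, complex)
    l = np.asarray(learned_eigs, complex)
    if t.shape != l.shape:
        raise ValueError(f"eigenvalue sets must have equal cardinality "
                         f"({t.size} vs {l.size}); fit at the true dimension")
    D = np.abs(t[:, None] - l[None, :])
    r, c = linear_sum_assignment(D)
    return float(D[r, c].mean() / np.mean(np.abs(t)))


def forecast_curve(model, dataset, horizons) -> dict:
    """Held-out decoding/prediction metrics as a function of horizon.

    For each m the model filters on past (y, u) and rolls the state forward
    with the generative recursion, consuming future u but no future y.
    Divergent rollouts yield NaN entries rather than silent drops.
    """
    states = model.filter_sequence(dataset.y, dataset.u)
    out = {"horizon": [], "behavior_cc": [], "behavior_r2": [],
           "neural_cc": [], "neural_r2": []}
    for m in horizons:
        zhat, yhat = model.predict_observations(states, u=dataset.u, horizon=m)
        sl = slice(m, None)
        out["horizon"].append(int(m))
        if np.all(np.isfinite(zhat[sl])) and np.all(np.isfinite(yhat[sl])):
            out["behavior_cc"].append(metric_cc(zhat[sl], dataset.z[sl]))
            out["behavior_r2"].append(metric_r2(zhat[sl], dataset.z[sl]))
            out["neural_cc"].append(metric_cc(yhat[sl], dataset.y[sl]))
            out["neural_r2"].append(metric_r2(yhat[sl], dataset.y[sl]))
        else:
            for k in ("behavior_cc", "behavior_r2", "neural_cc", "neural_r2"):
                out[k].append(float("nan"))
    return out


@dataclass
class EvalReport:
    """Fold-level metrics with mean ± s.e.m. aggregation."""

    horizons: list
    folds: list = field(default_factory=list)   # list of dicts per fold
    meta: dict = field(default_factory=dict)

    def add_fold(self, fold_metrics: dict):
        self.folds.append(fold_metrics)

    def _collect(self, key, horizon):
        vals = []
        for f in self.folds:
            idx = f["horizon"].index(horizon)
            vals.append(f[key][idx])
        return np.asarray(vals, float)

    def summary(self) -> dict:
        out = {}
        for key in ("behavior_cc", "behavior_r2", "neural_cc", "neural_r2"):
            out[key] = {}
            for m in self.horizons:
                v = self._collect(key, m)
                sem = float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
                out[key][int(m)] = {"mean": float(v.mean()), "sem": sem,
                                    "values": v.tolist()}
        return out

    def to_json(self) -> dict:
        return {"horizons": [int(m) for m in self.horizons],
                "summary": self.summary(), "meta": self.meta,
                "n_folds": len(self.folds)}

    def fold_rows(self):
        """Flat rows (fold, horizon, metric, value) for CSV export."""
        rows = []
        for i, f in enumerate(self.folds):
            for j, m in enumerate(f["horizon"]):
                for key in ("behavior_cc", "behavior_r2", "neural_cc", "neural_r2"):
                    rows.append({"fold": i, "horizon": int(m), "metric": key,
                                 "value": float(f[key][j])})
        return rows


def cross_validate(dataset, config, n_folds: int = 2, n1: int = None,
                   n2: int = 0, n3: int = 0, horizons=(1,)) -> EvalReport:
    """Contiguous-block cross-validation of a full fit.

    For each fold the model is fitted (all configured stages) on the
    remaining data and evaluated on the held-out block; fold-level metrics
    are aggregated as mean ± s.e.m.
    """
    from .training import fit_braid

    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    if dataset.T // n_folds <= max(horizons) + 2:
        raise ValueError("folds too short for the longest requested horizon")
    dataset.assign_folds(n_folds)
    report = EvalReport(horizons=list(horizons),
                        meta={"variant": config.variant, "n1": n1, "n2": n2,
                              "n3": n3, "seed": config.seed,
                              "dataset_seed": dataset.seed})
    for fold in range(n_folds):
        train, test = dataset.split_fold(fold)
        model = fit_braid(train, n1=n1, n2=n2, n3=n3, config=config)
        report.add_fold(forecast_curve(model, test, horizons))
    return report
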