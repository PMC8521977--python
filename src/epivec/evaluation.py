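"""Log-space error metrics and the inter-group concordance statistic.

Incidence predictions are scored in log10 space: the mean absolute
error (MAE) there corresponds to a multiplicative error factor of
10^MAE on the incidence scale.  Ranking quality is measured by the
inter-group concordance ρ_c: within each group (by default all records
of one country), every pair of items is scored 1 if predictions and
truth order them the same way, 0 if reversed, and ½ if either variable
ties; the group score is the mean over pairs and ρ_c the unweighted
mean over groups, so 1 is a perfect common ordering and 0 a fully
reversed one.

Not-applicable predictions (NaN) — produced by baselines that cannot
encode an unseen entity — are excluded from every metric and counted
separately.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np


def mae_log(pred, truth) -> float:
    """Mean absolute error between log10-space predictions and targets."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError(f"length mismatch: {p.shape} vs {t.shape}")
    if p.size == 0:
        raise ValueError("empty input")
    if not (np.isfinite(p).all() and np.isfinite(t).all()):
        raise ValueError("non-finite values in input")
    return float(np.mean(np.abs(p - t)))


def error_factor(mae: float) -> float:
    """Multiplicative over/under-estimation factor 10^MAE (e.g. 0.2 → 1.58)."""
    if mae < 0:
        raise ValueError("mae must be >= 0")
    return float(10.0 ** mae)


def _group_concordance(pred: np.ndarray, truth: np.ndarray,
                       chunk: int = 2048) -> tuple[float, int]:
    """(score sum, pair count) over all unordered pairs in one group."""
    n = len(pred)
    total = 0.0
    n_pairs = n * (n - 1) // 2
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        dp = pred[start:stop, None] - pred[None, :]
        dt = truth[start:stop, None] - truth[None, :]
        sp = np.sign(dp)
        st = np.sign(dt)
        score = np.where((sp == 0) | (st == 0), 0.5, (sp == st).astype(float))
        # keep strictly-upper-triangle pairs (j > global row index i)
        rows = np.arange(start, stop)[:, None]
        cols = np.arange(n)[None, :]
        total += float(score[cols > rows].sum())
    return total, n_pairs


def concordance(pred, truth, group_of=None) -> float:
    """Inter-group concordance ρ_c in [0, 1].

    Parameters
    ----------
    group_of
        Optional per-item group key; when absent all items form a single
        group.  Groups of size 1 are excluded with a warning; if every
        group is excluded the statistic is undefined and a ValueError is
        raised.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    if p.shape != t.shape:
        raise ValueError("length mismatch between pred and truth")
    if group_of is None:
        group_of = np.zeros(len(p), dtype=int)
    group_of = np.asarray(group_of)
    if len(group_of) != len(p):
        raise ValueError("group_of length mismatch")
    scores = []
    for g in np.unique(group_of):
        idx = group_of == g
        if idx.sum() < 2:
            warnings.warn(f"group {g!r} has fewer than 2 items; excluded from rho_c")
            continue
        total, n_pairs = _group_concordance(p[idx], t[idx])
        scores.append(total / n_pairs)
    if not scores:
        raise ValueError("no group with >= 2 items; rho_c undefined")
    return float(np.mean(scores))


def residual_bins(pred, truth, bin_width: float = 1.0) -> list[dict]:
    """Bin items by the predicted incidence exponent; per-bin residual stats.

    Each bin (floor of predicted log10 value, in ``bin_width`` exponent
    units) reports the signed-residual mean (positive = overestimate),
    the MAE, the residual standard deviation, and the item count.
    """
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    resid = p - t
    bin_idx = np.floor(p / bin_width).astype(int)
    out = []
    for b in np.unique(bin_idx):
        sel = bin_idx == b
        r = resid[sel]
        out.append({
            "bin_exponent": float(b * bin_width),
            "mean_residual": float(r.mean()),
            "mae": float(np.abs(r).mean()),
            "sd": float(r.std()),
            "n": int(sel.sum()),
        })
    return out


def stratified_report(pred, truth, strata) -> dict:
    """Per-stratum MAE and concordance (e.g. by age group or disease class)."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    strata = np.asarray(strata)
    if len(strata) != len(p):
        raise ValueError("strata length mismatch")
    report = {}
    for s in np.unique(strata):
        sel = strata == s
        n = int(sel.sum())
        entry = {"mae": mae_log(p[sel], t[sel]), "n": n}
        if n >= 2:
            entry["concordance"] = concordance(p[sel], t[sel])
        else:
            entry["concordance"] = None
            entry["flag"] = "n<2"
        report[str(s)] = entry
    return report


@dataclass
class EvaluationReport:
    """Pooled evaluation of one cross-validated experiment."""

    mae: float
    error_factor: float
    concordance: float
    n_scored: int
    n_not_applicable: int
    per_stratum: dict = field(default_factory=dict)
    residual_bins: list = field(default_factory=list)
    concordance_group: str = "country"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1, sort_keys=True)

    def summary(self) -> str:
        if self.n_scored == 0:
            return f"all {self.n_not_applicable} rows not applicable (N/A)"
        return (f"MAE={self.mae:.3f} (x{self.error_factor:.2f}), "
                f"rho_c={self.concordance:.3f}, "
                f"n={self.n_scored} scored / {self.n_not_applicable} N/A")


def evaluate(pred, truth, group_of=None, strata=None,
             concordance_group_name: str = "country") -> EvaluationReport:
    """Score pooled predictions, excluding NaN (not-applicable) rows."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    ok = np.isfinite(p)
    n_na = int((~ok).sum())
    if not ok.any():
        return EvaluationReport(mae=float("nan"), error_factor=float("nan"),
                                concordance=float("nan"), n_scored=0,
                                n_not_applicable=n_na,
                                concordance_group=concordance_group_name)
    m = mae_log(p[ok], t[ok])
    groups = None if group_of is None else np.asarray(group_of)[ok]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = concordance(p[ok], t[ok], groups)
    per_stratum = {}
    if strata is not None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            per_stratum = stratified_report(p[ok], t[ok], np.asarray(strata)[ok])
    return EvaluationReport(
        mae=m, error_factor=error_factor(m), concordance=rho,
        n_scored=int(ok.sum()), n_not_applicable=n_na,
        per_stratum=per_stratum, residual_bins=residual_bins(p[ok], t[ok]),
        concordance_group=concordance_group_name,
    )
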