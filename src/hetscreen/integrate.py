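"""Naive-Bayes integration of feature channels.

Each channel is calibrated against a labelled benchmark: a ROC sweep
over its raw values yields, at every operating threshold, the true and
false positive rates.  A variant's raw channel value is treated as the
operating threshold, and the channel contributes
``log2(TPR / FPR)`` — the log-likelihood ratio of the evidence under
the damaging vs benign hypotheses.  The combined functional-impact
score is

    log2(O_prior) + sum_i log2(TPR_i / FPR_i)

over the channels present for the variant (absent channels contribute
nothing).  Rates are smoothed with a half-count continuity correction
so no term is infinite.  The prior odds default to 1 — only the ranking
matters — so a score of 0 means the evidence is neutral and each bit
doubles the odds that the variant is damaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

CALIBRATION_SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ChannelCalibration:
    """One channel's ROC sweep against the labelled benchmark.

    ``thresholds`` are the distinct oriented scores in decreasing
    order; ``tp``/``fp`` are the benchmark positives/negatives at or
    above each threshold.  ``direction`` is +1 when larger raw values
    indicate damage, -1 when smaller do (auto-detected so the oriented
    AUC is always >= 0.5).
    """

    name: str
    direction: int
    thresholds: np.ndarray
    tp: np.ndarray
    fp: np.ndarray
    n_pos: int
    n_neg: int
    auc: float

    def operating_point(self, raw_value: float) -> tuple[float, float]:
        """Smoothed (TPR, FPR) with the raw value as the call threshold.

        The call set is every benchmark item scoring at least as
        damaging as the variant; rates get a half-count continuity
        correction so both lie strictly inside (0, 1).
        """
        v = self.direction * raw_value
        # thresholds descending: count how many sweep values are >= v
        idx = np.searchsorted(-self.thresholds, -v, side="right")
        tp = float(self.tp[idx - 1]) if idx > 0 else 0.0
        fp = float(self.fp[idx - 1]) if idx > 0 else 0.0
        tpr = (tp + 0.5) / (self.n_pos + 1.0)
        fpr = (fp + 0.5) / (self.n_neg + 1.0)
        return tpr, fpr

    @property
    def tpr(self) -> np.ndarray:
        """Unsmoothed sweep TPR, with the (0, 0) endpoint prepended."""
        return np.concatenate([[0.0], self.tp / self.n_pos, [1.0]])

    @property
    def fpr(self) -> np.ndarray:
        return np.concatenate([[0.0], self.fp / self.n_neg, [1.0]])


@dataclass(frozen=True)
class Calibration:
    channels: Mapping[str, ChannelCalibration] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "schema_version": CALIBRATION_SCHEMA_VERSION,
            "channels": {
                name: {
                    "direction": c.direction,
                    "thresholds": c.thresholds.tolist(),
                    "tp": c.tp.tolist(),
                    "fp": c.fp.tolist(),
                    "n_pos": c.n_pos,
                    "n_neg": c.n_neg,
                    "auc": c.auc,
                }
                for name, c in self.channels.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Calibration":
        with open(path) as fh:
            payload = json.load(fh)
        channels = {
            name: ChannelCalibration(
                name=name,
                direction=int(d["direction"]),
                thresholds=np.asarray(d["thresholds"], dtype=float),
                tp=np.asarray(d["tp"], dtype=float),
                fp=np.asarray(d["fp"], dtype=float),
                n_pos=int(d["n_pos"]),
                n_neg=int(d["n_neg"]),
                auc=float(d["auc"]),
            )
            for name, d in payload["channels"].items()
        }
        return cls(channels)


def _calibrate_channel(name: str, scores: np.ndarray, labels: np.ndarray) -> ChannelCalibration:
    auc_raw = roc_auc_score(labels, scores)
    direction = 1 if auc_raw >= 0.5 else -1
    oriented = direction * scores
    order = np.argsort(-oriented, kind="stable")
    s, y = oriented[order], labels[order]
    thresholds = -np.unique(-s)  # distinct oriented scores, descending
    cum_tp = np.cumsum(y)
    cum_fp = np.cumsum(~y)
    # for each distinct threshold t, tp/fp = items with oriented score >= t
    idx = np.searchsorted(-s, -thresholds, side="right") - 1
    return ChannelCalibration(
        name=name,
        direction=direction,
        thresholds=thresholds,
        tp=cum_tp[idx].astype(float),
        fp=cum_fp[idx].astype(float),
        n_pos=int(labels.sum()),
        n_neg=int((~labels).sum()),
        auc=float(max(auc_raw, 1.0 - auc_raw)),
    )


def roc_calibrate(
    scores: pd.DataFrame, labels: Sequence[bool] | np.ndarray
) -> Calibration:
    """Calibrate every score column against binary labels.

    ``scores`` has one column per channel (NaN = channel absent for
    that benchmark variant); ``labels`` is True for damaging.  Channel
    direction is auto-detected from the benchmark, and the resulting
    sweep depends only on the ranks of the raw values, so calibration
    is invariant to strictly monotone transforms.
    """
    y = np.asarray(labels, dtype=bool)
    if y.all() or not y.any():
        raise ValueError("benchmark must contain both positives and negatives")
    channels: dict[str, ChannelCalibration] = {}
    for name in scores.columns:
        x = np.asarray(scores[name], dtype=float)
        mask = np.isfinite(x)
        if not (y[mask].any() and (~y[mask]).any()):
            raise ValueError(f"channel {name!r} lacks both classes")
        channels[name] = _calibrate_channel(name, x[mask], y[mask])
    return Calibration(channels)


@dataclass(frozen=True)
class IntegratedScore:
    variant_id: str
    combined: float
    n_channels: int
    terms: Mapping[str, float]


def integrated_score(
    vector: Mapping[str, float],
    calibration: Calibration,
    o_prior: float = 1.0,
    variant_id: str = "",
) -> IntegratedScore:
    """Combine one variant's channels into the functional-impact score.

    Channels present in ``vector`` (non-NaN) must be calibrated; each
    contributes ``log2(TPR/FPR)`` at its operating point and the terms
    add to ``log2(o_prior)``.
    """
    if o_prior <= 0:
        raise ValueError("o_prior must be positive")
    terms: dict[str, float] = {}
    for name, value in vector.items():
        if value is None or (isinstance(value, float) and not np.isfinite(value)):
            continue
        cc = calibration.channels.get(name)
        if cc is None:
            raise ValueError(f"channel {name!r} present but not calibrated")
        tpr, fpr = cc.operating_point(float(value))
        terms[name] = float(np.log2(tpr / fpr))
    return IntegratedScore(
        variant_id=variant_id,
        combined=float(np.log2(o_prior) + sum(terms.values())),
        n_channels=len(terms),
        terms=terms,
    )


def integrate_table(
    features: pd.DataFrame,
    calibration: Calibration,
    o_prior: float = 1.0,
    id_column: str = "variant_id",
) -> pd.DataFrame:
    """Integrated scores for a feature table (one row per variant)."""
    channel_cols = [c for c in features.columns if c in calibration.channels]
    rows = []
    for _, row in features.iterrows():
        s = integrated_score(
            {c: row[c] for c in channel_cols}, calibration, o_prior,
            variant_id=str(row[id_column]) if id_column in features.columns else "",
        )
        rows.append({id_column: s.variant_id, "impact_score": s.combined,
                     "n_channels": s.n_channels})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float | None
    fdr: float
    fpr: float
    attainable: bool


def select_threshold(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    max_fdr: float = 0.01,
    max_fpr: float = 0.05,
) -> ThresholdResult:
    """Smallest score cut-off meeting empirical FDR and FPR bounds.

    Sweeps the distinct labelled scores as call thresholds (call =
    score >= threshold); FDR is the false-call fraction among calls and
    FPR the called fraction among negatives, both empirical on the
    labelled set.  Returns an unattainable result (threshold None)
    rather than raising when no cut-off satisfies both bounds.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    best: ThresholdResult | None = None
    for t in np.unique(s):  # ascending: first hit is the smallest threshold
        called = s >= t
        n_called = int(called.sum())
        if n_called == 0:
            continue
        fp = int((called & ~y).sum())
        fdr = fp / n_called
        fpr = fp / max(int((~y).sum()), 1)
        # a bound of 1 (or more) excludes nothing, so it always passes
        ok_fdr = max_fdr >= 1.0 or fdr < max_fdr
        ok_fpr = max_fpr >= 1.0 or fpr < max_fpr
        if ok_fdr and ok_fpr:
            best = ThresholdResult(float(t), fdr, fpr, True)
            break
    if best is None:
        return ThresholdResult(None, float("nan"), float("nan"), False)
    return best


def enrichment_curves(
    scored: pd.DataFrame,
    impact_threshold: float,
    het_bins: Sequence[int] = (41, 60, 100, 150, 250, 10**9),
    max_hom: int = 10,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fraction of high-impact variants vs het count and vs hom count.

    ``scored`` needs columns ``impact_score``, ``het`` and ``hom``.
    Curve 1 bins the hom = 0 variants by het count (bin edges
    ``[0, het_bins...)``) and reports the fraction whose impact score
    meets the threshold; curve 2 reports the same fraction per hom
    count (0..max_hom).  Empty bins are reported with NaN fractions.
    """
    edges = [0, *het_bins]
    rows = []
    hom0 = scored[scored["hom"] == 0]
    for lo, hi in zip(edges[:-1], edges[1:]):
        sub = hom0[(hom0["het"] >= lo) & (hom0["het"] < hi)]
        rows.append({
            "het_min": lo, "het_max": hi, "n": len(sub),
            "frac_impact": float((sub["impact_score"] >= impact_threshold).mean())
            if len(sub) else float("nan"),
        })
    by_het = pd.DataFrame(rows)

    rows = []
    for hom in range(0, max_hom + 1):
        sub = scored[scored["hom"] == hom]
        rows.append({
            "hom": hom, "n": len(sub),
            "frac_impact": float((sub["impact_score"] >= impact_threshold).mean())
            if len(sub) else float("nan"),
        })
    by_hom = pd.DataFrame(rows)
    return by_het, by_hom
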