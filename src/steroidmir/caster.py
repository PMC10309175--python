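"""Cross-sectional Asthma STEroid Response (CASTER) composite phenotype.

CASTER summarises five cross-sectional clinical measures of how well a
child's asthma is controlled on inhaled corticosteroids: oral steroid
courses, asthma-related ED visits/hospitalisations, pre-bronchodilator
FEV1 (% predicted), methacholine airway hyper-responsiveness (a PC20
surrogate, higher = less reactive), and bronchodilator response (BDR,
% FEV1 change). Each feature is oriented so that larger means better
response, z-standardised, and collapsed to a single score; the cohort
is then dichotomised at the mean score into good (> mean) and poor
(<= mean) responders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import DegenerateInputError

#: the five constituent measures with their response orientation
#: (+1: higher raw value = better steroid response)
CASTER_FEATURES: dict[str, int] = {
    "oral_steroid_courses": -1,
    "ed_visits": -1,
    "fev1_pct_pred": +1,
    "airway_hyperresponsiveness": +1,
    "bdr_pct": -1,
}

POOR, GOOD = "poor", "good"


class InsufficientDataError(ValueError):
    """Fewer complete subjects than the scoring method needs."""


@dataclass
class CasterResult:
    """Per-subject composite score, cohort mean threshold, and class."""

    scores: pd.Series  # indexed by subject_id, complete-case subjects only
    threshold: float
    classes: pd.Series  # "good" / "poor", same index
    method: str

    @property
    def poor_mask(self) -> pd.Series:
        return self.classes == POOR

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"caster_score": self.scores, "responder_class": self.classes}
        ).rename_axis("subject_id")


def _oriented_z(table: pd.DataFrame) -> pd.DataFrame:
    """Complete-case, orientation-flipped, z-standardised feature matrix."""
    missing = [c for c in CASTER_FEATURES if c not in table.columns]
    if missing:
        raise KeyError(f"clinical table lacks CASTER features: {missing}")
    feats = table[list(CASTER_FEATURES)].astype(float)
    feats = feats.dropna(axis=0, how="any")
    if feats.shape[0] < 3:
        raise InsufficientDataError(
            f"need >= 3 subjects with complete CASTER features, have {feats.shape[0]}"
        )
    oriented = feats * pd.Series(CASTER_FEATURES, dtype=float)
    sd = oriented.std(ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = list(sd.index[(sd == 0) | sd.isna()])
        raise DegenerateInputError(f"zero-variance CASTER feature(s): {bad}")
    return (oriented - oriented.mean()) / sd


def compute_caster(table: pd.DataFrame, method: str = "pca") -> CasterResult:
    """Score subjects and dichotomise at the cohort mean.

    Parameters
    ----------
    table : clinical table indexed by subject_id, containing the five
        CASTER constituent columns (see :data:`CASTER_FEATURES`).
        Subjects missing any constituent are excluded from scoring.
    method : ``"pca"`` — first principal component of the oriented,
        standardised feature matrix, sign-fixed to correlate positively
        with oriented FEV1; or ``"pls_distance"`` — negated Euclidean
        distance to the best observed oriented profile (an alternative
        backend with the same output contract).

    Notes
    -----
    Good responders are strictly above the mean score; ties at the mean
    are classified poor.
    """
    Z = _oriented_z(table)
    if method == "pca":
        cov = np.cov(Z.to_numpy(), rowvar=False, ddof=1)
        evals, evecs = np.linalg.eigh(cov)
        w = evecs[:, np.argmax(evals)]
        raw = Z.to_numpy() @ w
        # deterministic sign: score rises with oriented FEV1
        fev_idx = list(CASTER_FEATURES).index("fev1_pct_pred")
        r = np.corrcoef(raw, Z.to_numpy()[:, fev_idx])[0, 1]
        if r < 0:
            raw = -raw
        scores = pd.Series(raw, index=Z.index, name="caster_score")
    elif method == "pls_distance":
        ideal = Z.to_numpy().max(axis=0)
        d = np.linalg.norm(Z.to_numpy() - ideal, axis=1)
        scores = pd.Series(-d, index=Z.index, name="caster_score")
    else:
        raise ValueError(f"unknown CASTER method: {method!r}")

    threshold = float(scores.mean())
    classes = pd.Series(
        np.where(scores > threshold, GOOD, POOR), index=scores.index, name="responder_class"
    )
    return CasterResult(scores=scores, threshold=threshold, classes=classes, method=method)


def caster_group_sizes(result: CasterResult) -> tuple[int, int]:
    """Return ``(n_poor, n_good)``; sums to the number of scored subjects."""
    if len(result.classes) == 0:
        raise InsufficientDataError("empty CASTER result")
    n_poor = int((result.classes == POOR).sum())
    return n_poor, len(result.classes) - n_poor
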