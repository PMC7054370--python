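"""Biomarker preprocessing and reproducibility QC.

Pipeline order is fixed: detection-limit imputation, urinary-creatinine
normalisation of urine markers, rank-based Gaussianisation.  Markers are
excluded when the intraclass correlation over blinded duplicate aliquots is
below 0.4 or when more than 99% of readings are identical (which happens
when nearly all readings fall below the detection limit and are imputed to
the same value).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import squareform

ICC_MIN = 0.4
IDENTICAL_MAX = 0.99


def icc_duplicates(pairs) -> float:
    """One-way random-effects intraclass correlation, ICC(1,1), for paired
    aliquots: (MSB - MSW) / (MSB + MSW) from the one-way ANOVA decomposition.

    Pairs with a missing reading in either aliquot are dropped.
    """
    a = np.asarray(pairs, dtype=float)
    if a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("pairs must be an (n, 2) array")
    a = a[np.isfinite(a).all(axis=1)]
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least two complete pairs")
    grand = a.mean()
    means = a.mean(axis=1)
    msb = 2.0 * np.sum((means - grand) ** 2) / (n - 1)
    msw = np.sum((a - means[:, None]) ** 2) / n
    if msb + msw == 0:
        return float("nan")
    return float((msb - msw) / (msb + msw))


def impute_below_lod(values, detection_limit: float):
    """Replace readings below the detection limit (including missing-coded
    below-LOD readings, NaN) by half the detection limit."""
    if detection_limit <= 0:
        raise ValueError("detection limit must be positive")
    v = np.asarray(values, dtype=float).copy()
    below = ~np.isfinite(v) | (v < detection_limit)
    v[below] = detection_limit / 2.0
    return v


def normalise_urine(values, urinary_creatinine):
    """Divide urine readings by same-sample urinary creatinine (mmol/l).

    Samples with missing urinary creatinine get a missing ratio; creatinine
    must be positive where present.
    """
    v = np.asarray(values, dtype=float)
    uc = np.asarray(urinary_creatinine, dtype=float)
    if np.any(uc[np.isfinite(uc)] <= 0):
        raise ValueError("urinary creatinine must be positive")
    out = np.where(np.isfinite(uc), v / uc, np.nan)
    return out


def gaussianise(values):
    """Rank-based inverse-normal transform (Blom offset 3/8, ties averaged),
    then centred and scaled to unit SD.  Monotone in the input."""
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 3:
        raise ValueError("need at least 3 non-missing values")
    x = v[finite]
    if np.all(x == x[0]):
        raise ValueError("constant input cannot be Gaussianised")
    ranks = stats.rankdata(x, method="average")
    q = stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25))
    q = (q - q.mean()) / q.std()
    out = np.full(v.shape, np.nan)
    out[finite] = q
    return out


@dataclass
class MarkerQC:
    name: str
    icc: float
    identical_fraction: float
    below_lod_fraction: float
    included: bool
    reason: str = ""


@dataclass
class QCReport:
    markers: list = field(default_factory=list)

    @property
    def included_names(self):
        return [m.name for m in self.markers if m.included]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(m) for m in self.markers]).set_index("name")


def run_qc(panel, gaussianise_output: bool = True):
    """Full QC pass over a biomarker panel.

    Returns ``(report, processed)`` where ``processed`` is a DataFrame
    (participants x included markers) after LOD imputation, urine
    normalisation and (optionally) Gaussianisation.
    """
    dup_index = {pid: i for i, pid in enumerate(panel.participant_ids)}
    report = QCReport()
    columns = {}
    for j, name in enumerate(panel.marker_names):
        raw = panel.values[:, j]
        below = ~np.isfinite(raw) | (raw < panel.detection_limit[j])
        imputed = impute_below_lod(raw, panel.detection_limit[j])
        dup_primary = np.array([imputed[dup_index[pid]] for pid in panel.duplicate_ids])
        dup_second = impute_below_lod(panel.duplicate_values[:, j],
                                      panel.detection_limit[j])
        # ICC on the log scale: assay readings are right-skewed
        icc = icc_duplicates(np.column_stack([np.log(dup_primary),
                                              np.log(dup_second)]))
        _, counts = np.unique(imputed, return_counts=True)
        identical = counts.max() / len(imputed)
        included, reason = True, ""
        if identical > IDENTICAL_MAX:
            included, reason = False, f">{IDENTICAL_MAX:.0%} identical readings"
        elif not (icc >= ICC_MIN):
            included, reason = False, f"ICC {icc:.2f} < {ICC_MIN}"
        report.markers.append(MarkerQC(name, float(icc), float(identical),
                                       float(below.mean()), included, reason))
        if included:
            vals = imputed
            if panel.compartment[j] == "urine":
                vals = normalise_urine(vals, panel.urinary_creatinine)
            columns[name] = gaussianise(vals) if gaussianise_output else vals
    processed = pd.DataFrame(columns, index=panel.participant_ids)
    return report, processed


def clustered_correlation(matrix: pd.DataFrame):
    """Pearson correlation matrix reordered by average-linkage hierarchical
    clustering on distance 1 - r; returns (ordered correlation, leaf order).

    Constant markers are excluded with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 markers")
    keep = matrix.std() > 0
    if not keep.all():
        import warnings

        warnings.warn(f"excluding constant markers: {list(matrix.columns[~keep])}")
        matrix = matrix.loc[:, keep]
    r = matrix.corr().to_numpy()
    dist = squareform(np.clip(1.0 - r, 0.0, None), checks=False)
    order = leaves_list(average(dist))
    names = [matrix.columns[i] for i in order]
    ordered = pd.DataFrame(r[np.ix_(order, order)], index=names, columns=names)
    return ordered, names
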