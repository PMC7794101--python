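"""Plate-level data cleaning and normalization for targeted metabolomics.

The cleaning pipeline mirrors standard practice for Biocrates-style plate
designs with paper blanks and replicated medium-level QC (QC2) wells:

1. **Per-plate limit of detection.**  For metabolite *m* on plate *p* the
   LOD is the median of the raw paper-blank values on that plate
   (``LOD_{m,p}``); LODs are never shared across plates.
2. **Detection filter.**  A metabolite is kept only when at least 80 % of
   raw sample measurements exceed the plate-specific LOD in at least one of
   the two matched groups (cases, controls); the fraction threshold is
   configurable.  A strict variant requiring both groups to pass is
   available.
3. **Plate correction.**  ``A_{m,p}`` is the median of the QC2 replicate
   values strictly above LOD; dividing by the metabolite target value gives
   the per-plate correction factor ``C_{m,p} = A_{m,p} / TV_m``.
4. **Normalization.**  ``Norm = Raw / C_{m,p}``, putting every plate on the
   target-value scale; by construction the per-plate median of above-LOD
   normalized QC2 values equals ``TV_m`` exactly.
5. **Reproducibility filter.**  The coefficient of variation of the pooled
   normalized QC2 replicates across all plates (n-1 standard deviation over
   mean) must not exceed 25 % (configurable).

Sub-LOD sample values that survive the metabolite-level detection filter are
retained as measured; no imputation is performed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "QcError",
    "QcThresholds",
    "QcReport",
    "validate_plate_table",
    "compute_lod",
    "lod_filter",
    "plate_correction",
    "normalize",
    "cv_filter",
    "run_qc",
]

PLATE_COLUMNS = ["plate", "well", "sample_id", "role", "metabolite", "raw_uM"]
ROLES = ("sample", "blank", "QC1", "QC2", "QC3")


class QcError(ValueError):
    """Raised for structurally invalid plate tables or impossible QC stages."""


@dataclass(frozen=True)
class QcThresholds:
    """Filter thresholds; defaults follow the study protocol."""

    lod_frac: float = 0.20      # max tolerated fraction of values <= LOD
    cv_max: float = 0.25        # max QC2 coefficient of variation
    lod_both_groups: bool = False  # strict variant: both groups must pass

    def __post_init__(self) -> None:
        if not 0 <= self.lod_frac <= 1:
            raise QcError(f"lod_frac must be in [0,1], got {self.lod_frac}")
        if self.cv_max <= 0:
            raise QcError(f"cv_max must be positive, got {self.cv_max}")


@dataclass
class QcReport:
    """Machine-readable audit trail of the cleaning pipeline.

    ``verdicts`` assigns every panel metabolite exactly one of ``kept``,
    ``dropped_lod``, ``dropped_cv`` or ``dropped_correction`` (no usable QC2
    median on some plate), together with the triggering statistic.
    """

    lod: pd.Series                    # index (metabolite, plate)
    lod_fractions: pd.DataFrame       # index metabolite; frac_cases, frac_controls
    qc2_median: pd.Series             # A_{m,p}, index (metabolite, plate)
    correction: pd.Series             # C_{m,p}, index (metabolite, plate)
    cv: pd.Series                     # index metabolite (kept-after-LOD only)
    verdicts: pd.DataFrame            # index metabolite; verdict, detail
    thresholds: QcThresholds = field(default_factory=QcThresholds)

    def kept(self) -> list[str]:
        return list(self.verdicts.index[self.verdicts["verdict"] == "kept"])

    def funnel(self) -> dict[str, int]:
        counts = self.verdicts["verdict"].value_counts().to_dict()
        counts.setdefault("kept", 0)
        return counts

    def to_json(self, path: str | Path) -> None:
        def _pairs(s: pd.Series) -> list:
            return [[m, p, None if not np.isfinite(v) else v]
                    for (m, p), v in s.items()]

        payload = {
            "thresholds": {
                "lod_frac": self.thresholds.lod_frac,
                "cv_max": self.thresholds.cv_max,
                "lod_both_groups": self.thresholds.lod_both_groups,
            },
            "lod": _pairs(self.lod),
            "qc2_median": _pairs(self.qc2_median),
            "correction": _pairs(self.correction),
            "lod_fractions": self.lod_fractions.reset_index().to_dict("records"),
            "cv": {m: v for m, v in self.cv.items()},
            "verdicts": self.verdicts.reset_index().to_dict("records"),
            "funnel": self.funnel(),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1)

    def summary(self) -> str:
        f = self.funnel()
        total = int(self.verdicts.shape[0])
        lines = [
            f"panel metabolites        {total}",
            f"dropped: detection (LOD) {f.get('dropped_lod', 0)}",
            f"dropped: no usable QC2   {f.get('dropped_correction', 0)}",
            f"dropped: QC2 CV          {f.get('dropped_cv', 0)}",
            f"kept                     {f['kept']}",
        ]
        return "\n".join(lines)


def validate_plate_table(plates: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, roles, value signs and key uniqueness."""
    missing = [c for c in PLATE_COLUMNS if c not in plates.columns]
    if missing:
        raise QcError(f"plate table missing columns {missing}")
    bad_roles = set(plates["role"].unique()) - set(ROLES)
    if bad_roles:
        raise QcError(f"unknown well roles {sorted(bad_roles)}")
    if (plates["raw_uM"] < 0).any():
        raise QcError("negative raw concentrations present")
    if plates.duplicated(["plate", "well", "metabolite"]).any():
        raise QcError("duplicate (plate, well, metabolite) rows")
    return plates


def compute_lod(plates: pd.DataFrame) -> pd.Series:
    """Per-plate LOD: median raw blank value per (metabolite, plate).

    Even blank counts use the midpoint of the two central order statistics.
    Raises if any metabolite present on a plate has no blank well there.
    """
    blanks = plates[plates["role"] == "blank"]
    if blanks.empty:
        raise QcError("no blank wells in plate table")
    lod = blanks.groupby(["metabolite", "plate"])["raw_uM"].median()
    lod.name = "lod"
    present = plates.groupby(["metabolite", "plate"]).size()
    missing = present.index.difference(lod.index)
    if len(missing) > 0:
        m, p = missing[0]
        raise QcError(f"metabolite {m!r} has no blank wells on plate {p!r} "
                      f"({len(missing)} such combinations)")
    return lod


def _sample_flags(plates: pd.DataFrame, samples: pd.DataFrame,
                  lod: pd.Series) -> pd.DataFrame:
    """Sample rows annotated with case status and their plate-specific LOD."""
    rows = plates[plates["role"] == "sample"]
    if rows.empty:
        raise QcError("no sample wells in plate table")
    status = samples.set_index("sample_id")["case"]
    unmapped = set(rows["sample_id"]) - set(status.index)
    if unmapped:
        raise QcError(f"sample wells without sample-sheet entry: "
                      f"{sorted(unmapped)[:5]}...")
    out = rows.merge(lod.rename("lod"), left_on=["metabolite", "plate"],
                     right_index=True, how="left")
    if out["lod"].isna().any():
        m = out.loc[out["lod"].isna(), ["metabolite", "plate"]].iloc[0]
        raise QcError(f"no LOD for metabolite {m['metabolite']!r} on plate "
                      f"{m['plate']!r}")
    out["case"] = out["sample_id"].map(status).astype(int)
    return out


def lod_filter(plates: pd.DataFrame, samples: pd.DataFrame, lod: pd.Series,
               thresholds: QcThresholds = QcThresholds()) -> pd.DataFrame:
    """Detection-rate filter on raw sample values.

    Returns a frame indexed by metabolite with the fraction of values at or
    below LOD among cases and controls, and a ``keep`` flag: kept when the
    fraction is <= ``lod_frac`` in at least one group (or in both groups if
    ``lod_both_groups``).
    """
    flagged = _sample_flags(plates, samples, lod)
    flagged["at_or_below"] = flagged["raw_uM"] <= flagged["lod"]
    frac = (flagged.groupby(["metabolite", "case"])["at_or_below"]
            .mean().unstack("case"))
    frac.columns = ["frac_controls" if c == 0 else "frac_cases"
                    for c in frac.columns]
    for col in ("frac_cases", "frac_controls"):
        if col not in frac:
            raise QcError(f"cannot apply detection filter: no "
                          f"{'cases' if 'cases' in col else 'controls'} present")
    t = thresholds.lod_frac
    if thresholds.lod_both_groups:
        frac["keep"] = (frac["frac_cases"] <= t) & (frac["frac_controls"] <= t)
    else:
        frac["keep"] = (frac["frac_cases"] <= t) | (frac["frac_controls"] <= t)
    return frac[["frac_cases", "frac_controls", "keep"]]


def plate_correction(plates: pd.DataFrame, target_values: dict[str, float],
                     lod: pd.Series) -> tuple[pd.Series, pd.Series]:
    """QC2-based correction factors C_{m,p} = A_{m,p} / TV_m.

    ``A_{m,p}`` is the median of QC2 raw values strictly above the plate
    LOD.  Returns ``(correction, qc2_median)`` indexed by (metabolite,
    plate); combinations without any usable QC2 value carry NaN and are
    reported upstream as ``dropped_correction``.
    """
    qc2 = plates[plates["role"] == "QC2"]
    if qc2.empty:
        raise QcError("no QC2 wells in plate table")
    qc2 = qc2.merge(lod.rename("lod"), left_on=["metabolite", "plate"],
                    right_index=True, how="left")
    usable = qc2[qc2["raw_uM"] > qc2["lod"]]
    a = usable.groupby(["metabolite", "plate"])["raw_uM"].median()
    # reindex over every (m, p) that has QC2 wells so failures are visible
    full_idx = pd.MultiIndex.from_frame(
        qc2[["metabolite", "plate"]].drop_duplicates())
    a = a.reindex(full_idx.sortlevel()[0])
    a.name = "qc2_median"
    tv = a.index.get_level_values("metabolite").map(target_values)
    if tv.isna().any():
        m = a.index[np.where(tv.isna())[0][0]][0]
        raise QcError(f"no target value for metabolite {m!r}")
    if (np.asarray(tv) <= 0).any():
        raise QcError("non-positive target value")
    c = a / np.asarray(tv, dtype=float)
    c.name = "correction"
    return c, a


def normalize(plates: pd.DataFrame, correction: pd.Series) -> pd.DataFrame:
    """Divide raw values by the plate correction factor.

    Rows of metabolites absent from ``correction`` are dropped; a
    non-positive correction factor is an error.
    """
    c = correction.dropna()
    if (c <= 0).any():
        bad = c[c <= 0].index[0]
        raise QcError(f"non-positive correction factor for {bad}")
    out = plates.merge(c.rename("_c"), left_on=["metabolite", "plate"],
                       right_index=True, how="inner").copy()
    out["norm_uM"] = out["raw_uM"] / out["_c"]
    return out.drop(columns="_c")


def cv_filter(normalized: pd.DataFrame, threshold: float = 0.25) -> pd.DataFrame:
    """Coefficient of variation of pooled normalized QC2 values.

    CV_m = sample SD (n-1) / mean over all QC2 replicates of all plates.
    Metabolites with CV above the threshold, or with non-positive mean, are
    dropped.
    """
    qc2 = normalized[normalized["role"] == "QC2"]
    if qc2.empty:
        raise QcError("no QC2 wells in normalized table")
    g = qc2.groupby("metabolite")["norm_uM"]
    mean, sd = g.mean(), g.std(ddof=1)
    cv = sd / mean
    out = pd.DataFrame({"cv": cv})
    out["keep"] = (mean > 0) & (cv <= threshold)
    out.loc[mean <= 0, "cv"] = np.nan
    return out


def run_qc(plates: pd.DataFrame, samples: pd.DataFrame,
           target_values: dict[str, float],
           thresholds: QcThresholds = QcThresholds(),
           ) -> tuple[pd.DataFrame, QcReport]:
    """Full cleaning pipeline: LOD -> detection filter -> plate correction ->
    normalization -> CV filter.

    Returns the samples-only wide matrix (rows = sample ids, columns = kept
    metabolites, normalized µM) and the :class:`QcReport`.  Metabolites in
    ``target_values`` define the panel; plate-table metabolites must be a
    subset.
    """
    validate_plate_table(plates)
    panel_names = list(target_values)
    extra = set(plates["metabolite"]) - set(panel_names)
    if extra:
        raise QcError(f"plate table contains off-panel metabolites "
                      f"{sorted(extra)[:5]}...")

    lod = compute_lod(plates)
    frac = lod_filter(plates, samples, lod, thresholds)
    verdict = pd.Series("kept", index=pd.Index(panel_names, name="metabolite"))
    detail = pd.Series("", index=verdict.index, dtype=object)
    absent = verdict.index.difference(frac.index)
    if len(absent) > 0:
        raise QcError(f"panel metabolites absent from plate samples: "
                      f"{list(absent)[:5]}...")
    lod_fail = frac.index[~frac["keep"]]
    verdict.loc[lod_fail] = "dropped_lod"
    detail.loc[lod_fail] = [
        f"frac<=LOD cases {frac.at[m, 'frac_cases']:.3f}, "
        f"controls {frac.at[m, 'frac_controls']:.3f}" for m in lod_fail
    ]

    empty_idx = pd.MultiIndex.from_arrays([[], []],
                                          names=["metabolite", "plate"])
    survivors = [m for m in panel_names if verdict[m] == "kept"]
    sub = plates[plates["metabolite"].isin(survivors)]
    if not survivors:
        correction = pd.Series(dtype=float, index=empty_idx, name="correction")
        qc2_median = pd.Series(dtype=float, index=empty_idx, name="qc2_median")
    else:
        correction, qc2_median = plate_correction(sub, target_values, lod)
    # a metabolite unusable on any plate is dropped entirely
    bad = correction[correction.isna()].index.get_level_values("metabolite")
    for m in pd.unique(bad):
        verdict[m] = "dropped_correction"
        plates_bad = correction.loc[m][correction.loc[m].isna()].index.tolist()
        detail[m] = f"no QC2 above LOD on plate(s) {plates_bad}"

    survivors = [m for m in survivors if verdict[m] == "kept"]
    normed = normalize(sub[sub["metabolite"].isin(survivors)], correction)
    if survivors:
        cv = cv_filter(normed, thresholds.cv_max)
    else:
        cv = pd.DataFrame({"cv": pd.Series(dtype=float),
                           "keep": pd.Series(dtype=bool)})
        cv.index.name = "metabolite"
    cv_fail = cv.index[~cv["keep"]]
    verdict.loc[cv_fail] = "dropped_cv"
    detail.loc[cv_fail] = [
        "QC2 mean <= 0" if not np.isfinite(cv.at[m, 'cv'])
        else f"CV {cv.at[m, 'cv']:.3f}" for m in cv_fail
    ]

    kept = [m for m in panel_names if verdict[m] == "kept"]
    mat = (normed[(normed["role"] == "sample")
                  & normed["metabolite"].isin(kept)]
           .pivot(index="sample_id", columns="metabolite", values="norm_uM")
           .reindex(columns=kept))
    mat.index.name = "sample_id"

    report = QcReport(
        lod=lod,
        lod_fractions=frac,
        qc2_median=qc2_median,
        correction=correction,
        cv=cv["cv"],
        verdicts=pd.DataFrame({"verdict": verdict, "detail": detail}),
        thresholds=thresholds,
    )
    return mat, report
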