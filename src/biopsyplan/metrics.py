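"""Clinical biopsy outcome metrics and between-policy comparison.

Per episode the following are reported:

* **HR** — hit rate, the fraction of fired needles intersecting the lesion;
* **CCL** — total cancer core length in mm, summed over fired needles;
* **N.CCL** — CCL normalised by the maximum CCL attainable in the volume,
  taken as (number of planned needles) x (longest lesion chord along the
  needle axis);
* **N.Coverage** — needle spread normalised by lesion size,
  ``std_x * std_y * pi / Area_L`` with population standard deviations of the
  fired-needle world coordinates and the lesion's transverse projected area;
* **CCL coefficient** — Pearson correlation between lesion size (voxels)
  and measured CCL across cases.

Policies are compared metric-by-metric with paired Student t-tests at
alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .environment import NEEDLES_PER_PLAN, EpisodeResult
from .geometry import NeedleRecord
from .phantoms_io import NEEDLE_AXIS, MaskVolume, PatientCase

__all__ = [
    "MetricsReport",
    "hit_rate",
    "ccl_total",
    "n_ccl",
    "max_needle_axis_chord",
    "projected_area_mm2",
    "n_coverage",
    "ccl_coefficient",
    "build_report",
    "compare_policies",
]


def hit_rate(records: list[NeedleRecord]) -> float:
    """Hits / fired; NaN (with a warning) when nothing was fired."""
    fired = sum(r.fired for r in records)
    if fired == 0:
        warnings.warn("hit_rate undefined: no fired needles", stacklevel=2)
        return float("nan")
    return sum(r.hit for r in records) / fired


def ccl_total(records: list[NeedleRecord]) -> float:
    """Total cancer core length (mm) over fired needles."""
    return float(sum(r.ccl_mm for r in records if r.fired))


def max_needle_axis_chord(lesion: MaskVolume) -> float:
    """Longest lesion chord along the needle axis, in mm (voxel count per
    transverse column x axial spacing)."""
    counts = lesion.voxels.sum(axis=NEEDLE_AXIS)
    return float(counts.max()) * lesion.spacing[NEEDLE_AXIS]


def n_ccl(
    records: list[NeedleRecord],
    case: PatientCase,
    n_needles: int = NEEDLES_PER_PLAN,
) -> float:
    """CCL normalised by the maximum attainable CCL in this volume.

    The denominator is ``n_needles`` ideally placed needles of unlimited core
    length, each sampling the lesion's longest axial chord; ``n_needles=1``
    gives the alternative single-needle normalisation.
    """
    chord = max_needle_axis_chord(case.lesion)
    if chord == 0:
        raise ValueError("empty lesion")
    return ccl_total(records) / (n_needles * chord)


def projected_area_mm2(lesion: MaskVolume) -> float:
    """Area of the lesion projected onto the transverse plane (mm^2)."""
    proj = lesion.voxels.any(axis=NEEDLE_AXIS)
    in_plane = [d for d in range(3) if d != NEEDLE_AXIS]
    voxel_area = lesion.spacing[in_plane[0]] * lesion.spacing[in_plane[1]]
    return float(proj.sum()) * voxel_area


def n_coverage(records: list[NeedleRecord], case: PatientCase) -> float:
    """std_x * std_y * pi / Area_L over fired-needle positions.

    Population (divide-by-n) standard deviations of the fired needles' world
    x and y coordinates. NaN with fewer than two fired needles.
    """
    fired = [r for r in records if r.fired]
    if len(fired) < 2:
        warnings.warn("n_coverage undefined: fewer than 2 fired needles", stacklevel=2)
        return float("nan")
    xs = np.array([r.node_xy_mm[0] for r in fired])
    ys = np.array([r.node_xy_mm[1] for r in fired])
    area = projected_area_mm2(case.lesion)
    return float(xs.std() * ys.std() * np.pi / area)


def ccl_coefficient(lesion_sizes_voxels, ccls_mm) -> float:
    """Pearson correlation between lesion size (voxels) and CCL across cases."""
    sizes = np.asarray(lesion_sizes_voxels, dtype=float)
    ccls = np.asarray(ccls_mm, dtype=float)
    if sizes.size < 3:
        raise ValueError("need at least 3 cases for a correlation")
    if np.ptp(sizes) == 0 or np.ptp(ccls) == 0:
        warnings.warn("ccl_coefficient undefined for constant input", stacklevel=2)
        return float("nan")
    return float(stats.pearsonr(sizes, ccls).statistic)


@dataclass
class MetricsReport:
    """Per-episode metric table plus aggregate summaries for one policy."""

    per_case: pd.DataFrame
    label: str = ""  # mismatch setting / policy label
    dispersion: str = "across-case std"

    METRICS = ("hr", "ccl_mm", "n_ccl", "n_coverage")

    def aggregate(self) -> dict:
        """Mean +/- std per metric (NaN-aware) and the CCL coefficient."""
        out: dict[str, float] = {}
        for m in self.METRICS:
            vals = self.per_case[m].to_numpy(dtype=float)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                out[f"{m}_mean"] = float(np.nanmean(vals))
                out[f"{m}_std"] = float(np.nanstd(vals))
        df = self.per_case
        if len(df) >= 3 and df["ccl_mm"].nunique() > 1 and df["lesion_voxels"].nunique() > 1:
            out["ccl_coefficient"] = ccl_coefficient(
                df["lesion_voxels"], df["ccl_mm"]
            )
        else:
            out["ccl_coefficient"] = float("nan")
        out["n_fired_total"] = int(df["n_fired"].sum())
        out["n_hits_total"] = int(df["n_hits"].sum())
        return out

    def to_csv(self, path) -> None:
        self.per_case.to_csv(path, index=False)


def build_report(
    results: list[EpisodeResult],
    cases: dict[str, PatientCase] | list[PatientCase],
    label: str = "",
    n_needles: int = NEEDLES_PER_PLAN,
) -> MetricsReport:
    """Aggregate episode results into a metrics report.

    ``cases`` maps case_id -> PatientCase (a list is converted)."""
    if isinstance(cases, list):
        cases = {c.case_id: c for c in cases}
    rows = []
    episode_counter: dict[str, int] = {}
    for res in results:
        case = cases[res.case_id]
        ep = episode_counter.get(res.case_id, 0)
        episode_counter[res.case_id] = ep + 1
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rows.append(
                {
                    "case_id": res.case_id,
                    "episode": ep,
                    "hr": hit_rate(res.records),
                    "ccl_mm": ccl_total(res.records),
                    "n_ccl": n_ccl(res.records, case, n_needles),
                    "n_coverage": n_coverage(res.records, case),
                    "n_fired": res.n_fired,
                    "n_hits": res.n_hits,
                    "total_reward": res.total_reward,
                    "termination": res.termination,
                    "lesion_voxels": int(case.lesion.voxels.sum()),
                }
            )
    return MetricsReport(per_case=pd.DataFrame(rows), label=label)


def compare_policies(
    report_a: MetricsReport,
    report_b: MetricsReport,
    alpha: float = 0.05,
    metrics: tuple[str, ...] = MetricsReport.METRICS,
) -> pd.DataFrame:
    """Paired t-tests per metric between two reports on the same cases.

    Rows are metrics with columns (metric, t, p, significant). Identical
    paired samples report t = 0, p = 1 (zero-variance differences carry no
    evidence). Raises if the reports are not paired on (case_id, episode).
    """
    key = ["case_id", "episode"]
    a = report_a.per_case.set_index(key).sort_index()
    b = report_b.per_case.set_index(key).sort_index()
    if not a.index.equals(b.index):
        raise ValueError("reports are not paired on the same (case, episode) set")
    rows = []
    for m in metrics:
        da = a[m].to_numpy(dtype=float)
        db = b[m].to_numpy(dtype=float)
        ok = ~(np.isnan(da) | np.isnan(db))
        diff = da[ok] - db[ok]
        if diff.size < 2 or np.allclose(diff, 0):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_rel(da[ok], db[ok])
        rows.append(
            {
                "metric": m,
                "t": float(t),
                "p": float(p),
                "significant": bool(p < alpha),
            }
        )
    return pd.DataFrame(rows)
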