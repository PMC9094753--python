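"""Readthrough efficiency and growth defect from kinetic plate-reader data.

The luciferase readthrough assay compares a reporter carrying a single
quadruplet codon ("quad") against an all-triplet control ("triplet"),
with qtRNA expression induced or uninduced.  To compensate for growth
differences, luminescence is read out at a common culture density
(OD600 = 0.5 by default, first upward crossing, linearly interpolated in
time), and percent quadruplet translation efficiency is

    100 * (QuadLum_induced - QuadLum_uninduced)
        / (TriLum - QuadLum_uninduced)

Toxicity is summarized as a growth-defect ratio: induced over uninduced
OD at the time the induced culture first reaches OD 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

TRIPLET_CONTROL = "TRIPLET_CONTROL"
QUAD = "QUAD"
INDUCED = "INDUCED"
UNINDUCED = "UNINDUCED"

#: Flag raised when a growth curve never reaches the OD threshold.
FLAG_OD_NOT_REACHED = "od_threshold_not_reached"


@dataclass
class WellSeries:
    """One well's kinetic trace plus its condition labels."""

    times: np.ndarray
    od600: np.ndarray
    luminescence: np.ndarray
    reporter: str            # TRIPLET_CONTROL or QUAD
    induction: str           # INDUCED or UNINDUCED
    replicate: str
    qtrna: str = ""
    codon: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od600 = np.asarray(self.od600, dtype=float)
        self.luminescence = np.asarray(self.luminescence, dtype=float)
        if not (len(self.times) == len(self.od600) == len(self.luminescence)):
            raise ValueError(f"well {self.well}: series lengths differ")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"well {self.well}: times must be strictly increasing")
        if np.any(self.od600 < 0):
            raise ValueError(f"well {self.well}: negative OD600")


@dataclass
class PlateKinetics:
    """A collection of well traces from one kinetic plate run."""

    wells: list[WellSeries]

    def select(self, reporter: str | None = None, induction: str | None = None
               ) -> list[WellSeries]:
        out = self.wells
        if reporter is not None:
            out = [w for w in out if w.reporter == reporter]
        if induction is not None:
            out = [w for w in out if w.induction == induction]
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for w in self.wells:
            for t, od, lum in zip(w.times, w.od600, w.luminescence):
                rows.append(
                    dict(well=w.well, time_h=t, od600=od, lum=lum,
                         reporter=w.reporter, induction=w.induction,
                         replicate=w.replicate, qtrna=w.qtrna, codon=w.codon)
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "PlateKinetics":
        wells = []
        keys = ["well", "reporter", "induction", "replicate", "qtrna", "codon"]
        for vals, grp in df.groupby(keys, sort=True, dropna=False):
            grp = grp.sort_values("time_h")
            meta = dict(zip(keys, vals))
            wells.append(
                WellSeries(
                    times=grp["time_h"].to_numpy(),
                    od600=grp["od600"].to_numpy(),
                    luminescence=grp["lum"].to_numpy(),
                    reporter=meta["reporter"],
                    induction=meta["induction"],
                    replicate=str(meta["replicate"]),
                    qtrna=str(meta["qtrna"]) if pd.notna(meta["qtrna"]) else "",
                    codon=str(meta["codon"]) if pd.notna(meta["codon"]) else "",
                    well=str(meta["well"]),
                )
            )
        return cls(wells=wells)


@dataclass
class EfficiencyResult:
    """Per-replicate and summary percent translation efficiency."""

    qtrna: str
    codon: str
    per_replicate: dict[str, float]
    mean: float
    sd: float
    n: int
    flags: dict[str, str] = field(default_factory=dict)


@dataclass
class GrowthDefectResult:
    """Induced/uninduced OD ratio at the induced OD-0.5 crossing time."""

    qtrna: str
    t_measure: float
    ratio: float
    per_replicate: dict[str, float] = field(default_factory=dict)
    flags: dict[str, str] = field(default_factory=dict)


def _first_crossing_time(times: np.ndarray, od: np.ndarray, threshold: float
                         ) -> float | None:
    """Time of the first upward crossing of *threshold*, interpolated.

    Returns the exact sample time when a point hits the threshold, and
    None when the threshold is never reached.
    """
    if od[0] >= threshold:
        return float(times[0])
    above = np.nonzero(od >= threshold)[0]
    if len(above) == 0:
        return None
    i = int(above[0])
    t0, t1 = times[i - 1], times[i]
    y0, y1 = od[i - 1], od[i]
    if y1 == threshold:
        return float(t1)
    return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))


def _interp_at(times: np.ndarray, values: np.ndarray, t: float) -> float:
    return float(np.interp(t, times, values))


def lum_at_od(series: WellSeries, od_threshold: float = 0.5) -> float | None:
    """Luminescence at the first upward crossing of *od_threshold*.

    Linear interpolation in time between the bracketing samples; an exact
    sample hit returns the sample value.  Returns None (flagged sentinel)
    when the series never reaches the threshold, so callers can skip the
    replicate rather than catch an exception.
    """
    t = _first_crossing_time(series.times, series.od600, od_threshold)
    if t is None:
        return None
    return _interp_at(series.times, series.luminescence, t)


def translation_efficiency(tri_lux: float, quad_induced: float,
                           quad_uninduced: float) -> float:
    """Percent quadruplet translation efficiency relative to the triplet control.

    May be negative (toxicity can depress the induced signal below the
    uninduced background).
    """
    denom = tri_lux - quad_uninduced
    if denom == 0:
        raise ZeroDivisionError(
            "triplet-control luminescence equals quad uninduced luminescence; "
            "efficiency undefined"
        )
    return 100.0 * (quad_induced - quad_uninduced) / denom


def efficiency_from_plate(plate: PlateKinetics, od_threshold: float = 0.5
                          ) -> EfficiencyResult:
    """Percent efficiency per replicate, then mean/SD across replicates.

    The triplet-control luminescence is the mean across all control wells
    at the OD threshold (a single normalizer); quad induced/uninduced
    wells are paired by replicate id.  Replicates in which any required
    series never reaches the threshold are excluded and flagged.
    """
    tri_wells = plate.select(reporter=TRIPLET_CONTROL)
    quad_ind = {w.replicate: w for w in plate.select(QUAD, INDUCED)}
    quad_unind = {w.replicate: w for w in plate.select(QUAD, UNINDUCED)}
    missing = []
    if not tri_wells:
        missing.append("triplet-control wells")
    if not quad_ind:
        missing.append("induced quad-reporter wells")
    if not quad_unind:
        missing.append("uninduced quad-reporter wells")
    if missing:
        raise ValueError("plate is missing: " + ", ".join(missing))

    flags: dict[str, str] = {}
    tri_vals = []
    for w in tri_wells:
        v = lum_at_od(w, od_threshold)
        if v is None:
            flags[f"control:{w.replicate}"] = FLAG_OD_NOT_REACHED
        else:
            tri_vals.append(v)
    if not tri_vals:
        raise ValueError("no triplet-control well reached the OD threshold")
    tri_lux = float(np.mean(tri_vals))

    per_rep: dict[str, float] = {}
    some_well = next(iter(quad_ind.values()))
    for rep in sorted(set(quad_ind) & set(quad_unind)):
        qi = lum_at_od(quad_ind[rep], od_threshold)
        qu = lum_at_od(quad_unind[rep], od_threshold)
        if qi is None or qu is None:
            flags[rep] = FLAG_OD_NOT_REACHED
            continue
        per_rep[rep] = translation_efficiency(tri_lux, qi, qu)

    vals = np.array(list(per_rep.values()), dtype=float)
    return EfficiencyResult(
        qtrna=some_well.qtrna,
        codon=some_well.codon,
        per_replicate=per_rep,
        mean=float(vals.mean()) if len(vals) else math.nan,
        sd=float(vals.std(ddof=1)) if len(vals) > 1 else 0.0 if len(vals) else math.nan,
        n=len(vals),
        flags=flags,
    )


def growth_defect(plate: PlateKinetics, od_threshold: float = 0.5
                  ) -> GrowthDefectResult:
    """Growth-defect ratio of qtRNA induction, per replicate then averaged.

    For each replicate pair of quad-reporter wells, t_measure is the first
    time the induced culture reaches the OD threshold; the ratio is
    OD_induced(t_measure) / OD_uninduced(t_measure) = threshold /
    OD_uninduced(t_measure).  If the induced culture never reaches the
    threshold, t_measure falls back to the final time point and the
    replicate is flagged.  Also reports 1 - ratio as the fractional
    density difference via ``1 - result.ratio`` (not stored).
    """
    quad_ind = {w.replicate: w for w in plate.select(QUAD, INDUCED)}
    quad_unind = {w.replicate: w for w in plate.select(QUAD, UNINDUCED)}
    if not quad_ind or not quad_unind:
        raise ValueError("growth_defect requires induced and uninduced quad wells")

    flags: dict[str, str] = {}
    ratios: dict[str, float] = {}
    t_measures = []
    some_well = next(iter(quad_ind.values()))
    for rep in sorted(set(quad_ind) & set(quad_unind)):
        wi, wu = quad_ind[rep], quad_unind[rep]
        t = _first_crossing_time(wi.times, wi.od600, od_threshold)
        if t is None:
            t = float(wi.times[-1])
            flags[rep] = FLAG_OD_NOT_REACHED
        od_i = _interp_at(wi.times, wi.od600, t)
        od_u = _interp_at(wu.times, wu.od600, t)
        if od_u <= 0:
            flags[rep] = "uninduced_od_nonpositive"
            continue
        ratios[rep] = od_i / od_u
        t_measures.append(t)

    vals = np.array(list(ratios.values()), dtype=float)
    return GrowthDefectResult(
        qtrna=some_well.qtrna,
        t_measure=float(np.mean(t_measures)) if t_measures else math.nan,
        ratio=float(vals.mean()) if len(vals) else math.nan,
        per_replicate=ratios,
        flags=flags,
    )


def crosstalk_matrix(
    results: Iterable[EfficiencyResult],
    on_target: dict[str, str] | None = None,
    orthogonality_factor: float = 3.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Assemble a qtRNA x reporter-codon efficiency matrix.

    *on_target* maps each qtRNA name to its own codon; by default it is
    parsed from ``qtRNA-<Aa>-<CODON>`` names.  A qtRNA is marked
    orthogonal iff its on-target mean efficiency exceeds every off-target
    efficiency in its row by at least *orthogonality_factor* (default 3x).
    Missing cells stay NaN and are ignored in the orthogonality test.
    """
    results = list(results)
    if not results:
        return pd.DataFrame(), pd.Series(dtype=bool)
    qtrnas = sorted({r.qtrna for r in results})
    codons = sorted({r.codon for r in results})
    mat = pd.DataFrame(np.nan, index=qtrnas, columns=codons)
    for r in results:
        mat.loc[r.qtrna, r.codon] = r.mean
    if on_target is None:
        on_target = {q: q.rsplit("-", 1)[-1] for q in qtrnas}
    ortho = {}
    for q in qtrnas:
        own = on_target.get(q)
        if own is None or own not in mat.columns or pd.isna(mat.loc[q, own]):
            ortho[q] = False
            continue
        on = mat.loc[q, own]
        off = mat.loc[q, [c for c in codons if c != own]].dropna()
        ortho[q] = bool((on > orthogonality_factor * off).all()) if len(off) else True
    return mat, pd.Series(ortho, name="orthogonal")
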