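"""Small numeric assays: DNA-fibre fork velocity and qPCR 2^-ΔΔCt.

Fibre assay: replication tracks are pulse-labelled with CldU then IdU (20 min
each by default) and measured in µm. With the B-form DNA conversion of
~2.59 kb per µm, fork velocity in kb/min is

    velocity = track_length_um * kb_per_um / total_label_minutes

qPCR: relative expression by the comparative-Ct method. Per sample,
ΔCt = Ct(target) − Ct(reference); ΔΔCt subtracts the mean ΔCt of the
calibrator samples; expression = 2^−ΔΔCt, so calibrator samples average to 1
in the geometric sense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stats import MannWhitneyResult, mann_whitney, median


@dataclass(frozen=True)
class FibreConfig:
    """Conversion constants for the fibre assay.

    ``kb_per_um``: kb of B-form DNA per µm of spread fibre (2.59 by
    convention). ``label_minutes``: total labelling time, i.e. the sum of the
    two pulses (2 x 20 min = 40 by default).
    """

    kb_per_um: float = 2.59
    label_minutes: float = 40.0

    def __post_init__(self) -> None:
        if self.kb_per_um <= 0 or self.label_minutes <= 0:
            raise ValueError("kb_per_um and label_minutes must be positive")


@dataclass(frozen=True)
class FibreTrack:
    """One labelled fibre: combined CldU+IdU track length in µm."""

    track_id: str
    length_um: float
    condition: str = ""

    def __post_init__(self) -> None:
        if not math.isfinite(self.length_um):
            raise ValueError(f"track {self.track_id}: non-finite length")
        if self.length_um < 0:
            raise ValueError(f"track {self.track_id}: negative length")


def fibre_velocity(track: FibreTrack | float, config: FibreConfig | None = None
                   ) -> float:
    """Fork velocity in kb/min from a track (or bare length in µm)."""
    config = config or FibreConfig()
    length = track.length_um if isinstance(track, FibreTrack) else float(track)
    if not math.isfinite(length) or length < 0:
        raise ValueError(f"invalid track length {length}")
    return length * config.kb_per_um / config.label_minutes


def velocities(tracks: list[FibreTrack], config: FibreConfig | None = None
               ) -> np.ndarray:
    config = config or FibreConfig()
    return np.array([fibre_velocity(t, config) for t in tracks])


@dataclass(frozen=True)
class ConditionComparison:
    median_a: float
    median_b: float
    test: MannWhitneyResult

    @property
    def pvalue(self) -> float:
        return self.test.pvalue


def compare_conditions(velocities_a, velocities_b) -> ConditionComparison:
    """Pooled per-fibre medians of two conditions plus a two-sided
    Mann-Whitney test."""
    a = np.asarray(velocities_a, dtype=float)
    b = np.asarray(velocities_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both conditions need at least one measurement")
    return ConditionComparison(median(a), median(b), mann_whitney(a, b))


def percent_change(baseline_median: float, new_median: float) -> float:
    """100 * (new - baseline) / baseline; baseline must be positive."""
    if baseline_median <= 0:
        raise ValueError(f"baseline must be positive, got {baseline_median}")
    return 100.0 * (new_median - baseline_median) / baseline_median


@dataclass(frozen=True)
class CtRecord:
    """One qPCR well."""

    sample_id: str
    gene: str
    ct: float
    is_reference: bool = False
    is_calibrator_sample: bool = False

    def __post_init__(self) -> None:
        if not math.isfinite(self.ct):
            raise ValueError(f"sample {self.sample_id}, gene {self.gene}: "
                             f"non-finite Ct")


def ddct_expression(records: list[CtRecord], target_gene: str) -> pd.DataFrame:
    """Relative expression of ``target_gene`` per sample by 2^-ΔΔCt.

    Technical replicate wells of the same (sample, gene) are averaged at the
    Ct level. Calibrator ΔCt values are combined by arithmetic mean
    (geometric mean of expression), so the calibrator group's expression
    averages to 1 geometrically.

    Returns a DataFrame with sample_id, delta_ct, delta_delta_ct, expression.
    """
    ref_ct: dict[str, list[float]] = {}
    tgt_ct: dict[str, list[float]] = {}
    calibrator: dict[str, bool] = {}
    for r in records:
        calibrator.setdefault(r.sample_id, r.is_calibrator_sample)
        if r.is_reference:
            ref_ct.setdefault(r.sample_id, []).append(r.ct)
        elif r.gene == target_gene:
            tgt_ct.setdefault(r.sample_id, []).append(r.ct)
    if not tgt_ct:
        raise ValueError(f"no records for target gene {target_gene!r}")
    rows = []
    for sample in tgt_ct:
        if sample not in ref_ct:
            raise ValueError(f"sample {sample!r} has no reference-gene record")
        dct = float(np.mean(tgt_ct[sample])) - float(np.mean(ref_ct[sample]))
        rows.append([sample, dct, calibrator[sample]])
    df = pd.DataFrame(rows, columns=["sample_id", "delta_ct", "is_calibrator"])
    cal = df.loc[df["is_calibrator"], "delta_ct"]
    if cal.empty:
        raise ValueError("no calibrator samples among the target-gene records")
    ddct = df["delta_ct"] - cal.mean()
    df["delta_delta_ct"] = ddct
    df["expression"] = np.power(2.0, -ddct)
    return df.drop(columns=["is_calibrator"])


def read_fibre_tsv(path: str) -> list[FibreTrack]:
    """TSV with columns track_id, condition, length_um."""
    df = pd.read_csv(path, sep="\t")
    return [FibreTrack(str(r.track_id), float(r.length_um), str(r.condition))
            for r in df.itertuples(index=False)]


def read_ct_tsv(path: str, reference_gene: str, calibrator_condition: str
                ) -> list[CtRecord]:
    """TSV with columns sample_id, condition, gene, ct."""
    df = pd.read_csv(path, sep="\t")
    return [CtRecord(str(r.sample_id), str(r.gene), float(r.ct),
                     is_reference=(str(r.gene) == reference_gene),
                     is_calibrator_sample=(str(r.condition) == calibrator_condition))
            for r in df.itertuples(index=False)]
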