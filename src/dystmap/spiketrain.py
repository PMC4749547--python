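"""Interspike-interval statistics for cerebellar single-unit recordings.

Per-cell statistics follow the definitions used for awake Purkinje-cell /
deep-cerebellar-nucleus (DCN) recordings in the dystonic mouse model:

* average firing rate — spike count divided by recorded time;
* predominant firing rate — reciprocal of the mode of the ISI histogram
  (burst-sensitive, unlike the average rate);
* CV ISI — sample standard deviation of the ISIs divided by their mean.

Cells are stratified by posture state (each cell belongs to exactly one
group), summarized as mean ± SEM per (cell class × genotype × posture)
group, and compared with nonparametric two-sample tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

CELL_CLASSES = ("Purkinje", "DCN")
POSTURES = ("none", "abnormal")

#: Published group means (mean, SEM, n cells) from awake recordings in the
#: dystonic mutant and wild-type mice; used as calibration targets for the
#: synthetic spike-train generator and as the fixed inputs for fold-ratio
#: arithmetic. Keys: (cell_class, group) with group in
#: {"WT", "mutant_no_posture", "mutant_abnormal"}.
REFERENCE_FIRING_TABLE: dict[tuple[str, str], dict[str, tuple[float, float] | int]] = {
    ("DCN", "WT"): {"n": 26, "average_fr": (37.4, 3.7),
                    "predominant_fr": (61.0, 6.9), "cv_isi": (0.677, 0.05)},
    ("DCN", "mutant_no_posture"): {"n": 42, "average_fr": (50.3, 5.9),
                                   "predominant_fr": (110.1, 13.8),
                                   "cv_isi": (0.751, 0.05)},
    ("DCN", "mutant_abnormal"): {"n": 56, "average_fr": (26.7, 2.9),
                                 "predominant_fr": (221.9, 20.9),
                                 "cv_isi": (1.272, 0.07)},
    ("Purkinje", "WT"): {"n": 61, "average_fr": (62.9, 2.8),
                         "predominant_fr": (83.2, 3.4), "cv_isi": (0.578, 0.02)},
    ("Purkinje", "mutant_no_posture"): {"n": 76, "average_fr": (73.6, 2.8),
                                        "predominant_fr": (98.7, 3.6),
                                        "cv_isi": (0.531, 0.01)},
    ("Purkinje", "mutant_abnormal"): {"n": 45, "average_fr": (62.7, 5.0),
                                      "predominant_fr": (103.8, 8.1),
                                      "cv_isi": (0.919, 0.07)},
}

DEFAULT_BIN_WIDTH = 0.001   # s; 1 ms linear ISI bins
DEFAULT_MAX_ISI = 1.0       # s; histogram range
MIN_SPIKES = 10             # below this a cell is excluded from summaries


@dataclass
class SpikeTrain:
    """Spike times of one cell over one recording epoch."""

    cell_id: str
    cell_class: str
    genotype: str            # "WT" or "mutant"
    posture_state: str       # "none" or "abnormal"
    times: np.ndarray        # s, strictly increasing
    duration: float          # s

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.times.size and (
            self.times[0] < 0
            or self.times[-1] > self.duration
            or np.any(np.diff(self.times) <= 0)
        ):
            raise ValueError(
                f"spike times of {self.cell_id} must be strictly increasing "
                f"within [0, duration]"
            )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def isis(self) -> np.ndarray:
        return np.diff(self.times)

    @property
    def group(self) -> str:
        if self.genotype == "WT":
            return "WT"
        return "mutant_abnormal" if self.posture_state == "abnormal" else "mutant_no_posture"


@dataclass(frozen=True)
class IsiStats:
    cell_id: str
    average_fr: float
    predominant_fr: float
    cv_isi: float
    n_spikes: int
    n_isi: int
    mode_isi: float
    bin_width: float


def average_firing_rate(train: SpikeTrain) -> float:
    """Spikes divided by recorded time (Hz)."""
    return train.n_spikes / train.duration


def predominant_firing_rate(
    train: SpikeTrain,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_isi: float = DEFAULT_MAX_ISI,
) -> float:
    """Reciprocal of the mode of the ISI histogram (Hz).

    ISIs are binned linearly on [0, max_isi]; the mode is the center of the
    fullest bin, ties broken toward the shortest ISI so that high-frequency
    bursts win. ISIs beyond max_isi are ignored.
    """
    return 1.0 / mode_isi(train, bin_width, max_isi)


def mode_isi(
    train: SpikeTrain,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_isi: float = DEFAULT_MAX_ISI,
) -> float:
    if train.n_spikes < 2:
        raise ValueError("mode ISI needs at least 2 spikes")
    isis = train.isis()
    isis = isis[isis <= max_isi]
    if isis.size == 0:
        raise ValueError("all ISIs exceed the histogram range")
    edges = np.arange(0.0, max_isi + bin_width, bin_width)
    counts, _ = np.histogram(isis, bins=edges)
    k = int(np.argmax(counts))  # argmax takes the first maximal bin: shortest ISI
    return (edges[k] + edges[k + 1]) / 2.0


def cv_isi(train: SpikeTrain) -> float:
    """Sample (n-1) standard deviation of the ISIs over their mean."""
    if train.n_spikes < 3:
        raise ValueError("CV ISI needs at least 3 spikes")
    isis = train.isis()
    return float(np.std(isis, ddof=1) / np.mean(isis))


def compute_isi_stats(
    train: SpikeTrain,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_isi: float = DEFAULT_MAX_ISI,
) -> IsiStats:
    m = mode_isi(train, bin_width, max_isi)
    return IsiStats(
        cell_id=train.cell_id,
        average_fr=average_firing_rate(train),
        predominant_fr=1.0 / m,
        cv_isi=cv_isi(train),
        n_spikes=train.n_spikes,
        n_isi=train.n_spikes - 1,
        mode_isi=m,
        bin_width=bin_width,
    )


STAT_COLUMNS = ("average_fr", "predominant_fr", "cv_isi")


def per_cell_table(
    trains: Sequence[SpikeTrain],
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_spikes: int = MIN_SPIKES,
) -> pd.DataFrame:
    """Per-cell statistics; cells below `min_spikes` are flagged, not scored."""
    rows = []
    for tr in trains:
        row = {
            "cell_id": tr.cell_id,
            "cell_class": tr.cell_class,
            "genotype": tr.genotype,
            "posture_state": tr.posture_state,
            "group": tr.group,
            "n_spikes": tr.n_spikes,
            "included": tr.n_spikes >= min_spikes,
        }
        if tr.n_spikes >= min_spikes:
            st = compute_isi_stats(tr, bin_width=bin_width)
            row.update(
                average_fr=st.average_fr,
                predominant_fr=st.predominant_fr,
                cv_isi=st.cv_isi,
                mode_isi=st.mode_isi,
            )
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_groups(
    trains: Sequence[SpikeTrain],
    bin_width: float = DEFAULT_BIN_WIDTH,
    min_spikes: int = MIN_SPIKES,
) -> pd.DataFrame:
    """Group summary: n cells and mean ± SEM per statistic.

    One row per (cell_class, group); groups with zero included cells get
    n=0 and NaN statistics.
    """
    if len(trains) == 0:
        raise ValueError("empty cohort")
    cells = per_cell_table(trains, bin_width=bin_width, min_spikes=min_spikes)
    cells = cells[cells["included"]]
    rows = []
    groups = ("WT", "mutant_no_posture", "mutant_abnormal")
    for cc, grp in itertools.product(CELL_CLASSES, groups):
        sub = cells[(cells["cell_class"] == cc) & (cells["group"] == grp)]
        row: dict = {"cell_class": cc, "group": grp, "n_cells": len(sub)}
        for col in STAT_COLUMNS:
            if len(sub) == 0:
                row[f"{col}_mean"], row[f"{col}_sem"] = np.nan, np.nan
            else:
                vals = sub[col].to_numpy()
                row[f"{col}_mean"] = float(np.mean(vals))
                row[f"{col}_sem"] = (
                    float(np.std(vals, ddof=1) / np.sqrt(len(vals)))
                    if len(vals) > 1 else np.nan
                )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_groups(
    values_a: Sequence[float],
    values_b: Sequence[float],
    method: str = "ks",
    exact_max_n: int = 8,
) -> tuple[float, float]:
    """Two-sample comparison; returns (statistic, p).

    method="ks": two-sample Kolmogorov-Smirnov, D = sup |ECDF difference|;
    the p-value is exact (equivalent to permutation enumeration) when both
    samples have at most `exact_max_n` observations, asymptotic otherwise.
    method="mw" (Mann-Whitney): exact U distribution for small samples
    without ties, normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    small = a.size <= exact_max_n and b.size <= exact_max_n
    if method == "ks":
        res = sps.ks_2samp(a, b, method="exact" if small else "asymp")
    elif method == "mw":
        ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        res = sps.mannwhitneyu(
            a, b, alternative="two-sided",
            method="exact" if (small and not ties) else "asymptotic",
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def compare_all(
    trains: Sequence[SpikeTrain],
    bin_width: float = DEFAULT_BIN_WIDTH,
    methods: Sequence[str] = ("ks", "mw"),
) -> pd.DataFrame:
    """All pairwise group comparisons per cell class and statistic."""
    cells = per_cell_table(trains, bin_width=bin_width)
    cells = cells[cells["included"]]
    pairs = [("WT", "mutant_no_posture"), ("WT", "mutant_abnormal"),
             ("mutant_no_posture", "mutant_abnormal")]
    rows = []
    for cc in CELL_CLASSES:
        for ga, gb in pairs:
            va = cells[(cells.cell_class == cc) & (cells.group == ga)]
            vb = cells[(cells.cell_class == cc) & (cells.group == gb)]
            if len(va) == 0 or len(vb) == 0:
                continue
            for col in STAT_COLUMNS:
                for m in methods:
                    stat, p = compare_groups(va[col], vb[col], method=m)
                    rows.append({"cell_class": cc, "group_a": ga, "group_b": gb,
                                 "statistic_name": col, "method": m,
                                 "statistic": stat, "p_value": p})
    return pd.DataFrame(rows)


def fold_ratios(summary: pd.DataFrame) -> pd.DataFrame:
    """Ratios of group means: mutant-abnormal over WT and over mutant-no-posture.

    Expects the frame produced by :func:`summarize_groups` (or any frame
    with cell_class/group and ``*_mean`` columns).
    """
    rows = []
    for cc in summary["cell_class"].unique():
        sub = summary[summary["cell_class"] == cc].set_index("group")
        for ref_grp, label in (("WT", "vs_WT"), ("mutant_no_posture", "vs_no_posture")):
            if "mutant_abnormal" not in sub.index or ref_grp not in sub.index:
                raise ValueError(f"missing group for fold ratio in {cc}")
            for col in STAT_COLUMNS:
                num = sub.loc["mutant_abnormal", f"{col}_mean"]
                den = sub.loc[ref_grp, f"{col}_mean"]
                rows.append({"cell_class": cc, "statistic_name": col,
                             "comparison": label, "ratio": float(num) / float(den)})
    return pd.DataFrame(rows)


def reference_summary_frame() -> pd.DataFrame:
    """The published group means as a `summarize_groups`-shaped frame."""
    rows = []
    for (cc, grp), d in REFERENCE_FIRING_TABLE.items():
        row = {"cell_class": cc, "group": grp, "n_cells": d["n"]}
        for col in STAT_COLUMNS:
            mean, sem = d[col]  # type: ignore[misc]
            row[f"{col}_mean"], row[f"{col}_sem"] = mean, sem
        rows.append(row)
    return pd.DataFrame(rows)
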