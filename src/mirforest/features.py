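"""The 34 descriptive features computed from an aligned, energy-annotated duplex.

Five categories: alignment (score, length), thermodynamic (duplex MFE),
structural (per-category column counts over the whole alignment), 20 nominal
position features (pairing category of alignment columns 1-20, counted from
the miRNA 5' end, gap columns included), and six seed features (MFE and
counts over columns 2-8, the seed window).  Positions beyond a short
alignment take the distinguished level ABSENT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .duplex import DuplexAlignment, PairCategory
from .thermo import EnergyModel, duplex_mfe, seed_mfe

logger = logging.getLogger(__name__)

SEED_START, SEED_END = 2, 8  # alignment columns, 1-based inclusive
N_POSITIONS = 20
ABSENT = "ABSENT"
POSITION_LEVELS = [c.name for c in PairCategory] + [ABSENT]

LABEL_TARGET = "TARGET"
LABEL_NON_TARGET = "NON_TARGET"
LABEL_COLUMN = "label"
ID_COLUMN = "pair_id"

ALIGNMENT_FEATURES = ["alignment_score", "alignment_length"]
THERMO_FEATURES = ["mfe_total"]
STRUCTURAL_FEATURES = [
    "count_gc_total",
    "count_au_total",
    "count_gu_total",
    "count_gap_total",
    "count_mismatch_total",
]
POSITION_FEATURES = [f"position_{k}" for k in range(1, N_POSITIONS + 1)]
SEED_FEATURES = [
    "mfe_seed",
    "count_gc_seed",
    "count_au_seed",
    "count_gu_seed",
    "count_gap_seed",
    "count_mismatch_seed",
]

FEATURE_NAMES: list[str] = (
    ALIGNMENT_FEATURES
    + THERMO_FEATURES
    + STRUCTURAL_FEATURES
    + POSITION_FEATURES
    + SEED_FEATURES
)

NUMERIC_FEATURES = (
    ALIGNMENT_FEATURES + THERMO_FEATURES + STRUCTURAL_FEATURES + SEED_FEATURES
)

#: Features with greatest impact on predictive accuracy, found by restricted
#: forward feature selection on the Gini-importance ranking.
TOP12 = [
    "alignment_score",
    "mfe_total",
    "count_gc_total",
    "count_au_total",
    "position_2",
    "position_4",
    "position_6",
    "position_7",
    "mfe_seed",
    "count_gc_seed",
    "count_au_seed",
    "count_gu_seed",
]

#: Features describing the seed window (miRNA positions 2-8): the six seed
#: category features plus the position features inside the window.
SEED_REGION_FEATURES = SEED_FEATURES + [f"position_{k}" for k in range(2, 9)]

CATEGORY_PRESETS = {
    "cat1": ALIGNMENT_FEATURES,
    "cat2": THERMO_FEATURES,
    "cat3": STRUCTURAL_FEATURES,
    "cat4": SEED_FEATURES,
    "cat5": POSITION_FEATURES,
}

SUBSET_PRESETS = {"all": FEATURE_NAMES, "top12": TOP12, **CATEGORY_PRESETS}

_COUNT_KEYS = {
    PairCategory.GC_MATCH: "gc",
    PairCategory.AU_MATCH: "au",
    PairCategory.GU_WOBBLE: "gu",
    PairCategory.GAP: "gap",
    PairCategory.MISMATCH: "mismatch",
}


def extract_features(
    alignment: DuplexAlignment, model: EnergyModel | None = None
) -> dict:
    """Compute the 34-feature vector of one duplex alignment."""
    model = model or EnergyModel()
    L = alignment.length
    if L < 8:
        raise ValueError("alignment too short for feature extraction (needs >= 8 columns)")
    vec: dict = {
        "alignment_score": float(alignment.score),
        "alignment_length": L,
    }
    vec["mfe_total"] = (
        float(alignment.mfe) if alignment.mfe is not None else duplex_mfe(alignment, model)
    )
    for key in _COUNT_KEYS.values():
        vec[f"count_{key}_total"] = 0
    for cat in alignment.categories:
        vec[f"count_{_COUNT_KEYS[cat]}_total"] += 1
    for k in range(1, N_POSITIONS + 1):
        vec[f"position_{k}"] = (
            alignment.categories[k - 1].name if k <= L else ABSENT
        )
    vec["mfe_seed"] = seed_mfe(alignment, model)
    for key in _COUNT_KEYS.values():
        vec[f"count_{key}_seed"] = 0
    for cat in alignment.categories[SEED_START - 1 : SEED_END]:
        vec[f"count_{_COUNT_KEYS[cat]}_seed"] += 1
    return {name: vec[name] for name in FEATURE_NAMES}


@dataclass
class FeatureTable:
    """Rows of (pair identifier, 34-feature vector, optional class label)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if ID_COLUMN not in self.frame.columns:
            self.frame = self.frame.copy()
            self.frame.insert(0, ID_COLUMN, [str(i) for i in range(len(self.frame))])
        if self.has_labels:
            labels = self.frame[LABEL_COLUMN]
            bad = set(labels.unique()) - {LABEL_TARGET, LABEL_NON_TARGET}
            if bad or labels.isna().any():
                raise ValueError(
                    "labels must be TARGET/NON_TARGET for every row or absent "
                    f"for all rows (got {sorted(map(str, bad))})"
                )
        ordered = [ID_COLUMN] + FEATURE_NAMES + (
            [LABEL_COLUMN] if self.has_labels else []
        )
        self.frame = self.frame[ordered].reset_index(drop=True)

    @classmethod
    def from_rows(
        cls,
        ids: list[str],
        vectors: list[dict],
        labels: Optional[list[str]] = None,
    ) -> "FeatureTable":
        frame = pd.DataFrame(vectors)
        frame.insert(0, ID_COLUMN, ids)
        if labels is not None:
            frame[LABEL_COLUMN] = labels
        return cls(frame)

    @property
    def has_labels(self) -> bool:
        return LABEL_COLUMN in self.frame.columns

    @property
    def features(self) -> pd.DataFrame:
        return self.frame[FEATURE_NAMES]

    @property
    def labels(self) -> Optional[pd.Series]:
        return self.frame[LABEL_COLUMN] if self.has_labels else None

    @property
    def ids(self) -> pd.Series:
        return self.frame[ID_COLUMN]

    def __len__(self) -> int:
        return len(self.frame)

    def select(self, names: list[str]) -> pd.DataFrame:
        unknown = [n for n in names if n not in FEATURE_NAMES]
        if unknown:
            raise KeyError(f"unknown features: {unknown}")
        return self.frame[names]


def scale_features(
    table: FeatureTable, params: Optional[dict] = None
) -> tuple[FeatureTable, dict]:
    """Standardize numeric features to mean 0, sd 1 (categoricals untouched).

    When ``params`` is given (from a previous call) it is applied as-is, so
    held-out data can be scaled with the training parameters.  Returns the
    scaled table and the parameters {column: (mean, sd)}.
    """
    frame = table.frame.copy()
    if params is None:
        params = {}
        for col in NUMERIC_FEATURES:
            mean = float(frame[col].mean())
            sd = float(frame[col].std(ddof=0))
            if sd == 0.0:
                logger.warning("constant numeric feature %r scaled to zeros", col)
            params[col] = (mean, sd)
    for col, (mean, sd) in params.items():
        frame[col] = (frame[col] - mean) / sd if sd > 0 else 0.0
    return FeatureTable(frame), params


def unscale_features(table: FeatureTable, params: dict) -> FeatureTable:
    """Invert :func:`scale_features` with the stored parameters."""
    frame = table.frame.copy()
    for col, (mean, sd) in params.items():
        frame[col] = frame[col] * sd + mean if sd > 0 else mean
    return FeatureTable(frame)


def feature_correlation(table: FeatureTable) -> pd.DataFrame:
    """Pearson correlation matrix over the 14 numeric features.

    Nominal position features are excluded (Pearson correlation is undefined
    on unordered categories).  Zero-variance features yield NaN markers.
    """
    if len(table) < 3:
        raise ValueError("need at least 3 rows to estimate correlations")
    numeric = table.frame[NUMERIC_FEATURES].astype(float)
    return numeric.corr(method="pearson")
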