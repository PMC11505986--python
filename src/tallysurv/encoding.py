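"""Visit-history tally encoding and design-matrix assembly.

The time-varying extension summarizes a patient's whole follow-up history
as a 76-dimensional tally vector appended to the time-fixed covariates:

* 46 counts of visits at which each treatment category was administered,
* 18 counts of visits at which each adverse-event category occurred,
* 6 counts of visits falling in each age bin
  (≤65, (65,70], (70,75], (75,80], (80,85], >85),
* 6 counts of visits falling in each comorbidity-index bin
  (≤2, (2,4], (4,6], (6,8], (8,10], >10).

By default tallies run from diagnosis to the end of follow-up.  Because
that makes the features depend on follow-up length, an ``as_of`` landmark
is also exposed: tallies then cover only visits with ``t <= as_of``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    Cohort,
    N_ADVERSE_EVENT_CATEGORIES,
    N_TREATMENT_CATEGORIES,
    VisitRecord,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AGE_BINS",
    "COMORBIDITY_BINS",
    "BinScheme",
    "HistoryTallies",
    "DesignMatrix",
    "assign_bin",
    "encode_history",
    "history_tallies_frame",
    "tally_column_names",
    "build_design_matrix",
    "FIXED_NUMERIC",
    "FIXED_CATEGORICAL",
]

FIXED_NUMERIC = ["age_dx", "comorbidity_dx"]
FIXED_CATEGORICAL = ["race", "marital", "stage", "grade", "laterality", "er", "pr", "her2"]

N_BINS = 6
N_TALLY = N_TREATMENT_CATEGORIES + N_ADVERSE_EVENT_CATEGORIES + 2 * N_BINS  # 76


@dataclass(frozen=True)
class BinScheme:
    """Six right-closed bins defined by five interior edges."""

    edges: tuple[float, ...]
    kind: str

    def __post_init__(self):
        if len(self.edges) != N_BINS - 1 or list(self.edges) != sorted(self.edges):
            raise ValueError("a bin scheme needs 5 strictly increasing edges")


AGE_BINS = BinScheme((65.0, 70.0, 75.0, 80.0, 85.0), "age")
COMORBIDITY_BINS = BinScheme((2.0, 4.0, 6.0, 8.0, 10.0), "comorbidity")


def assign_bin(value: float, scheme: BinScheme) -> int:
    """Bin index 1..6; boundary values fall in the lower bin."""
    if np.isnan(value):
        raise ValueError(f"cannot bin NaN {scheme.kind}")
    return int(np.searchsorted(scheme.edges, value, side="left")) + 1


@dataclass
class HistoryTallies:
    """The 76-dimensional visit-history summary for one patient."""

    tr: np.ndarray = field(default_factory=lambda: np.zeros(N_TREATMENT_CATEGORIES, dtype=np.int64))
    ae: np.ndarray = field(default_factory=lambda: np.zeros(N_ADVERSE_EVENT_CATEGORIES, dtype=np.int64))
    age_bins: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS, dtype=np.int64))
    comb_bins: np.ndarray = field(default_factory=lambda: np.zeros(N_BINS, dtype=np.int64))

    def vector(self) -> np.ndarray:
        return np.concatenate([self.tr, self.ae, self.age_bins, self.comb_bins])


def tally_column_names() -> list[str]:
    return (
        [f"tr_{j}" for j in range(1, N_TREATMENT_CATEGORIES + 1)]
        + [f"ae_{k}" for k in range(1, N_ADVERSE_EVENT_CATEGORIES + 1)]
        + [f"age_bin_{b}" for b in range(1, N_BINS + 1)]
        + [f"comb_bin_{b}" for b in range(1, N_BINS + 1)]
    )


def encode_history(visits: list[VisitRecord], as_of: float | str = "end") -> HistoryTallies:
    """Tally one patient's visit history up to the ``as_of`` landmark.

    A treatment administered at a visit counts once per visit regardless of
    how many claim lines recorded it; the same holds for adverse events.
    ``as_of="end"`` tallies the whole follow-up.
    """
    ids = {v.patient_id for v in visits}
    if len(ids) > 1:
        raise ValueError(f"visits span multiple patients: {sorted(ids)}")
    out = HistoryTallies()
    cutoff = np.inf if as_of == "end" else float(as_of)
    for v in visits:
        if v.t > cutoff:
            continue
        for j in v.treatments:
            out.tr[j - 1] += 1
        for k in v.adverse_events:
            out.ae[k - 1] += 1
        out.age_bins[assign_bin(v.age, AGE_BINS) - 1] += 1
        out.comb_bins[assign_bin(v.comorbidity_index, COMORBIDITY_BINS) - 1] += 1
    return out


def history_tallies_frame(cohort: Cohort, as_of: float | str = "end") -> pd.DataFrame:
    """Vectorized tallies for every patient; rows indexed by patient_id.

    Equivalent to calling :func:`encode_history` per patient (tested as
    such) but computed with pandas group-bys so large cohorts stay cheap.
    """
    pids = cohort.patients["patient_id"]
    cols = tally_column_names()
    v = cohort.visits
    if as_of != "end":
        v = v[v["t"] <= float(as_of)]
    out = pd.DataFrame(0, index=pids, columns=cols, dtype=np.int64)
    if len(v) == 0:
        return out

    def _code_counts(series: pd.Series, prefix: str, n_codes: int) -> None:
        s = series.astype(str).str.split(";").explode()
        s = s[s.str.len() > 0]
        if s.empty:
            return
        codes = s.astype(int).to_numpy()
        who = v.loc[s.index, "patient_id"].to_numpy()  # positional pairing
        tab = pd.crosstab(who, codes)
        for code in tab.columns:
            out.loc[tab.index, f"{prefix}_{code}"] += tab[code].to_numpy()

    _code_counts(v["treatments"], "tr", N_TREATMENT_CATEGORIES)
    _code_counts(v["adverse_events"], "ae", N_ADVERSE_EVENT_CATEGORIES)

    for col, scheme, prefix in (("age", AGE_BINS, "age_bin"),
                                ("comorbidity_index", COMORBIDITY_BINS, "comb_bin")):
        b = np.searchsorted(scheme.edges, v[col].to_numpy(dtype=float), side="left") + 1
        tab = pd.crosstab(v["patient_id"].to_numpy(), b)
        for bb in tab.columns:
            out.loc[tab.index, f"{prefix}_{bb}"] += tab[bb].to_numpy()
    return out


# ---------------------------------------------------------------------------
# design matrices


@dataclass
class DesignMatrix:
    """A standardized model matrix plus everything needed to re-apply the
    fitted transform to new rows (imputation medians, categorical levels,
    per-column mean/sd from the fit rows)."""

    values: np.ndarray
    column_names: list[str]
    encoding_mode: str  # "fixed" | "extended"
    patient_ids: list[str]
    numeric_medians: dict[str, float]
    categorical_levels: dict[str, list[str]]
    means: np.ndarray
    sds: np.ndarray
    continuous: np.ndarray  # mask of z-scored columns (numerics and tallies)
    as_of: float | str = "end"

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.column_names,
                            index=pd.Index(self.patient_ids, name="patient_id"))

    def transform_cohort(self, cohort: Cohort) -> np.ndarray:
        """Apply this fitted transform to another cohort's rows."""
        raw, names, _ = _raw_features(cohort, self.encoding_mode,
                                      self.numeric_medians, self.categorical_levels,
                                      self.as_of)
        assert names == self.column_names
        return _standardize(raw, self.means, self.sds)


def _one_hot(series: pd.Series, levels: list[str], col: str) -> np.ndarray:
    vals = series.astype(str).fillna("unknown")
    unseen = set(vals) - set(levels)
    if unseen:
        logger.info("column %s: unseen levels %s mapped to 'other'", col, sorted(unseen))
    mat = np.zeros((len(vals), len(levels) + 1))
    lookup = {lv: i for i, lv in enumerate(levels)}
    for r, val in enumerate(vals):
        mat[r, lookup.get(val, len(levels))] = 1.0
    return mat


def _raw_features(cohort: Cohort, mode: str, medians: dict[str, float],
                  levels: dict[str, list[str]], as_of):
    p = cohort.patients
    blocks, names, cont = [], [], []
    for col in FIXED_NUMERIC:
        x = pd.to_numeric(p[col], errors="coerce").fillna(medians[col]).to_numpy(dtype=float)
        blocks.append(x[:, None])
        names.append(col)
        cont.append(True)
    for col in FIXED_CATEGORICAL:
        oh = _one_hot(p[col], levels[col], col)
        blocks.append(oh)
        # "<other>" is the catch-all for levels unseen at fit time; the angle
        # brackets keep it distinct from any natural level value
        names.extend([f"{col}={lv}" for lv in levels[col]] + [f"{col}=<other>"])
        cont.extend([False] * oh.shape[1])
    if mode == "extended":
        tf = history_tallies_frame(cohort, as_of=as_of)
        blocks.append(tf.to_numpy(dtype=float))
        names.extend(tf.columns.tolist())
        cont.extend([True] * tf.shape[1])
    return np.hstack(blocks), names, np.array(cont)


def _standardize(raw: np.ndarray, means: np.ndarray, sds: np.ndarray) -> np.ndarray:
    out = raw - means
    nz = sds > 0
    out[:, nz] /= sds[nz]
    out[:, ~nz] = 0.0  # zero-variance columns map to all zeros, never NaN
    return out


def build_design_matrix(cohort: Cohort, mode: str = "fixed",
                        fit_rows: np.ndarray | None = None,
                        as_of: float | str = "end") -> DesignMatrix:
    """Assemble the model matrix for a cohort.

    ``fixed`` mode one-hot-encodes the categorical diagnosis covariates and
    keeps the two numeric ones; ``extended`` mode appends the 76 history
    tally columns.  All columns are z-scored with mean/sd computed on
    ``fit_rows`` only (default: all rows); missing numerics are imputed
    with the fit-row median, missing categoricals carry an explicit
    'unknown' level, and levels unseen at fit time map to 'other'.
    """
    if mode not in ("fixed", "extended"):
        raise ValueError(f"mode must be 'fixed' or 'extended', got {mode!r}")
    if cohort.n == 0:
        raise ValueError("cohort is empty")
    if fit_rows is None:
        fit_rows = np.arange(cohort.n)
    fit_rows = np.asarray(fit_rows)
    if fit_rows.size == 0:
        raise ValueError("fit_rows is empty")

    fit_p = cohort.patients.iloc[fit_rows]
    medians = {
        col: float(np.nanmedian(pd.to_numeric(fit_p[col], errors="coerce")))
        for col in FIXED_NUMERIC
    }
    levels = {col: sorted(fit_p[col].astype(str).unique()) for col in FIXED_CATEGORICAL}

    raw, names, cont = _raw_features(cohort, mode, medians, levels, as_of)
    # z-score only the continuous columns; one-hot indicators pass through
    means = np.where(cont, raw[fit_rows].mean(axis=0), 0.0)
    sds = np.where(cont, raw[fit_rows].std(axis=0, ddof=0), 1.0)
    values = _standardize(raw, means, sds)

    return DesignMatrix(
        values=values,
        column_names=names,
        encoding_mode=mode,
        patient_ids=cohort.patient_ids,
        numeric_medians=medians,
        categorical_levels=levels,
        means=means,
        sds=sds,
        continuous=cont,
        as_of=as_of,
    )
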