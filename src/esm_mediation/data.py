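"""Reading, validity filtering, aggregation and lagging of experience-sampling data.

An experience-sampling (ESM) dataset is a long-format table with one row per
scheduled prompt ("beep") per subject.  Subjects belong to one of three
groups indexing familial liability to psychosis (patients, first-degree
relatives, healthy controls).  Each beep carries momentary composites on a
1-7 Likert-type scale: stress (X), negative affect (M) and psychotic
experiences (Y), plus the subject-level covariates age and gender.

Validity of a beep follows standard ESM practice: a report completed more
than a fixed number of minutes (default 15) after the signal is excluded,
and subjects answering fewer than one-third of their scheduled beeps are
dropped entirely.  Lagged (t-1, t) pairs are formed only from immediately
adjacent valid beeps within the same day, so the nominal lag spacing
(~90 min) is preserved and overnight gaps never form a pair.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import IntegrityError, SchemaError

logger = logging.getLogger(__name__)

#: Group labels in increasing order of familial liability.
GROUPS = ("control", "relative", "patient")

#: Canonical column names of the long-format beep table.
COLUMNS = (
    "subject_id",
    "group",
    "day",
    "beep",
    "scheduled_time",
    "completed_time",
    "stress",
    "negative_affect",
    "psychotic_experiences",
    "age",
    "gender",
)

#: Composite score columns and their conventional mediation-model roles.
COMPOSITES = {
    "stress": "X",
    "negative_affect": "M",
    "psychotic_experiences": "Y",
}


@dataclass(frozen=True)
class EsmDesign:
    """Sampling design shared by every subject in a dataset."""

    beeps_per_day: int = 10
    n_days: int = 6
    day_start: str = "07:30"
    day_end: str = "22:30"

    @property
    def scheduled_beeps(self) -> int:
        return self.beeps_per_day * self.n_days


@dataclass
class EsmDataset:
    """Two-level container: beeps (level 1) nested in subjects (level 2).

    ``frame`` holds one row per beep with the canonical columns plus a
    boolean ``valid`` column.  Invalid rows are retained in the container
    but excluded from every analysis; dropped subjects are removed.
    """

    frame: pd.DataFrame
    design: EsmDesign = field(default_factory=EsmDesign)
    filter_report: dict = field(default_factory=dict)
    #: disabled by the generator's no-clipping mode, where latent scores
    #: intentionally leave the 1-7 response scale
    enforce_scale: bool = True

    def __post_init__(self) -> None:
        if "valid" not in self.frame.columns:
            self.frame = self.frame.copy()
            self.frame["valid"] = self.frame["completed_time"].notna()
        _check_invariants(self.frame, self.enforce_scale)

    @property
    def n_subjects(self) -> int:
        return self.frame["subject_id"].nunique()

    @property
    def subjects(self) -> pd.DataFrame:
        """One row per subject with group, age and gender."""
        cols = ["subject_id", "group", "age", "gender"]
        return self.frame[cols].drop_duplicates("subject_id").reset_index(drop=True)

    def valid_frame(self) -> pd.DataFrame:
        return self.frame[self.frame["valid"]].copy()

    def copy(self) -> "EsmDataset":
        return EsmDataset(
            self.frame.copy(), self.design, dict(self.filter_report),
            self.enforce_scale,
        )


@dataclass
class LaggedDataset:
    """Consecutive-beep (t-1, t) pairs within subject and day.

    ``frame`` has one row per pair with value columns ``X_lag, M_lag,
    Y_lag`` (beep t-1) and ``X_t, M_t, Y_t`` (beep t).
    """

    frame: pd.DataFrame
    design: EsmDesign = field(default_factory=EsmDesign)

    @property
    def n_pairs(self) -> int:
        return len(self.frame)


@dataclass
class AggregateTable:
    """Person-mean aggregates by group plus pairwise Welch comparisons."""

    group_table: pd.DataFrame
    comparisons: pd.DataFrame
    person_means: pd.DataFrame

    def to_json(self) -> dict:
        return {
            "groups": self.group_table.to_dict(orient="records"),
            "comparisons": self.comparisons.to_dict(orient="records"),
        }


def _check_invariants(frame: pd.DataFrame, enforce_scale: bool = True) -> None:
    dup = frame.duplicated(subset=["subject_id", "day", "beep"])
    if dup.any():
        offenders = frame.loc[dup, ["subject_id", "day", "beep"]]
        listing = "; ".join(
            f"subject {r.subject_id} day {r.day} beep {r.beep}"
            for r in offenders.head(10).itertuples()
        )
        raise IntegrityError(f"duplicate (subject, day, beep) rows: {listing}")
    for col in COMPOSITES if enforce_scale else ():
        vals = frame[col].dropna()
        if len(vals) and ((vals < 1) | (vals > 7)).any():
            bad = vals[(vals < 1) | (vals > 7)]
            raise IntegrityError(
                f"{col} outside the 1-7 scale for {len(bad)} rows "
                f"(first offending value {bad.iloc[0]!r})"
            )
    per_subj = frame.groupby("subject_id", observed=True)[["age", "gender"]].nunique()
    unstable = per_subj[(per_subj > 1).any(axis=1)]
    if len(unstable):
        raise IntegrityError(
            "age/gender vary within subject(s): "
            + ", ".join(map(str, unstable.index[:10]))
        )


def load_esm_table(
    path,
    schema: dict | None = None,
    design: EsmDesign | None = None,
    sep: str = ",",
) -> EsmDataset:
    """Read a delimited long-format beep table into an :class:`EsmDataset`.

    Parameters
    ----------
    path : str or file-like
        Delimited text file, one row per beep, ISO-8601 timestamps.
    schema : dict, optional
        Mapping from canonical column names (see :data:`COLUMNS`) to the
        column names used in the file.  Identity for omitted keys.
    design : EsmDesign, optional
        Sampling design; defaults to 10 beeps/day over 6 days.
    sep : str
        Field delimiter.

    Raises
    ------
    SchemaError
        If a mandatory column is missing after applying ``schema``.
    IntegrityError
        If (subject, day, beep) rows are duplicated or scores leave [1, 7].
    """
    schema = schema or {}
    raw = pd.read_csv(path, sep=sep)
    rename = {schema.get(c, c): c for c in COLUMNS}
    missing = [src for src in rename if src not in raw.columns]
    if missing:
        raise SchemaError(
            f"missing mandatory column(s): {', '.join(sorted(missing))}"
        )
    df = raw.rename(columns=rename)[list(COLUMNS)].copy()

    rejected = []
    grp = df["group"].astype(str).str.strip().str.lower()
    bad_group = ~grp.isin(GROUPS)
    day = pd.to_numeric(df["day"], errors="coerce")
    beep = pd.to_numeric(df["beep"], errors="coerce")
    bad_day = day.isna() | (day < 1) | (day != day.round())
    bad_beep = beep.isna() | (beep < 1) | (beep != beep.round())
    bad = bad_group | bad_day | bad_beep
    for idx in df.index[bad]:
        reasons = []
        if bad_group[idx]:
            reasons.append(f"unparseable group {df.at[idx, 'group']!r}")
        if bad_day[idx]:
            reasons.append(f"unparseable day {df.at[idx, 'day']!r}")
        if bad_beep[idx]:
            reasons.append(f"unparseable beep {df.at[idx, 'beep']!r}")
        rejected.append({"row": int(idx), "reason": "; ".join(reasons)})
    if rejected:
        logger.warning("rejected %d unparseable rows", len(rejected))
    df = df[~bad].copy()
    df["group"] = pd.Categorical(grp[~bad], categories=GROUPS)
    df["day"] = day[~bad].astype(int)
    df["beep"] = beep[~bad].astype(int)
    for col in ("scheduled_time", "completed_time"):
        df[col] = pd.to_datetime(df[col], errors="coerce")
    for col in (*COMPOSITES, "age"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df = df.reset_index(drop=True)

    ds = EsmDataset(df, design or EsmDesign())
    ds.filter_report["rejected_rows"] = rejected
    ds.filter_report["n_loaded"] = len(df)
    return ds


def apply_lateness_filter(ds: EsmDataset, max_delay: float = 15.0) -> EsmDataset:
    """Mark reports completed later than ``max_delay`` minutes as invalid.

    A delay of exactly ``max_delay`` is valid ("later than" read strictly).
    Missing completions are invalid; negative delays (completed before the
    signal) are flagged invalid with a warning rather than raising.
    The operation is idempotent and never revalidates records.
    """
    if ds.frame["scheduled_time"].isna().any():
        raise SchemaError("scheduled_time must be present for every record")
    out = ds.copy()
    f = out.frame
    delay = (f["completed_time"] - f["scheduled_time"]).dt.total_seconds() / 60.0
    negative = delay < 0
    if negative.any():
        warnings.warn(
            f"{int(negative.sum())} report(s) completed before the scheduled "
            "signal; marked invalid",
            stacklevel=2,
        )
    late = delay.isna() | (delay > max_delay) | negative
    before = int(f["valid"].sum())
    f["valid"] = f["valid"] & ~late
    out.filter_report["lateness"] = {
        "max_delay_min": max_delay,
        "n_invalidated": before - int(f["valid"].sum()),
    }
    return out


def apply_compliance_filter(ds: EsmDataset, min_fraction: float = 1 / 3) -> EsmDataset:
    """Drop subjects with fewer than ``min_fraction`` valid beeps.

    The denominator is the number of scheduled beeps implied by the design
    (beeps/day x days); a fraction of exactly ``min_fraction`` is retained
    ("at least one-third").  An empty result is allowed.
    """
    out = ds.copy()
    f = out.frame
    scheduled = ds.design.scheduled_beeps
    valid_counts = f.groupby("subject_id", observed=True)["valid"].sum()
    keep = valid_counts[valid_counts / scheduled >= min_fraction].index
    dropped = sorted(set(f["subject_id"]) - set(keep))
    out.frame = f[f["subject_id"].isin(keep)].reset_index(drop=True)
    out.filter_report["compliance"] = {
        "min_fraction": min_fraction,
        "n_subjects_dropped": len(dropped),
        "dropped_subjects": [str(s) for s in dropped[:50]],
    }
    if not len(out.frame):
        logger.warning("compliance filter removed every subject")
    return out


def compute_aggregates(ds: EsmDataset) -> AggregateTable:
    """Person-mean aggregates per group with pairwise Welch comparisons.

    Person means are taken over each subject's valid beeps only (per
    composite, using that composite's available values).  Group mean and
    s.d. are computed over person means; pairwise between-group differences
    carry Welch two-sample 95% confidence intervals.  Comparisons involving
    a group with fewer than two subjects are reported as undefined (NaN).
    """
    vf = ds.valid_frame()
    pm = (
        vf.groupby(["subject_id", "group"], observed=True)[list(COMPOSITES)]
        .mean()
        .reset_index()
    )

    rows = []
    for g in GROUPS:
        sub = pm[pm["group"] == g]
        row = {"group": g, "n": len(sub)}
        for c in COMPOSITES:
            row[f"{c}_mean"] = sub[c].mean() if len(sub) else np.nan
            row[f"{c}_sd"] = sub[c].std(ddof=1) if len(sub) > 1 else np.nan
        rows.append(row)
    group_table = pd.DataFrame(rows)

    comps = []
    pairs = [("patient", "control"), ("relative", "control"), ("patient", "relative")]
    for ga, gb in pairs:
        a = pm[pm["group"] == ga]
        b = pm[pm["group"] == gb]
        for c in COMPOSITES:
            xa, xb = a[c].dropna().to_numpy(), b[c].dropna().to_numpy()
            rec = {"comparison": f"{ga} v. {gb}", "measure": c}
            if len(xa) < 2 or len(xb) < 2:
                # point difference still defined with one subject per side;
                # the Welch CI and p-value are not
                diff = (
                    xa.mean() - xb.mean() if len(xa) and len(xb) else np.nan
                )
                rec.update(diff=diff, ci_lower=np.nan, ci_upper=np.nan, p=np.nan)
            else:
                diff = xa.mean() - xb.mean()
                se = np.sqrt(xa.var(ddof=1) / len(xa) + xb.var(ddof=1) / len(xb))
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
                # Welch-Satterthwaite df for the CI
                va, vb = xa.var(ddof=1) / len(xa), xb.var(ddof=1) / len(xb)
                df_w = (va + vb) ** 2 / (
                    va**2 / (len(xa) - 1) + vb**2 / (len(xb) - 1)
                )
                crit = stats.t.ppf(0.975, df_w)
                rec.update(
                    diff=diff,
                    ci_lower=diff - crit * se,
                    ci_upper=diff + crit * se,
                    p=p,
                )
            comps.append(rec)
    comparisons = pd.DataFrame(comps)
    return AggregateTable(group_table, comparisons, pm)


def build_lagged_pairs(ds: EsmDataset) -> LaggedDataset:
    """Form (t-1, t) pairs from immediately adjacent valid beeps.

    A pair is emitted for every (k, k+1) beep pair within a subject-day
    where both beeps are valid.  An invalid intermediate beep breaks the
    chain and overnight transitions never pair, so every pair spans one
    nominal ~90-min sampling interval.
    """
    vf = ds.valid_frame().sort_values(["subject_id", "day", "beep"])
    if not len(vf):
        return LaggedDataset(_empty_lagged_frame(), ds.design)
    nxt = vf.groupby(["subject_id", "day"], observed=True).shift(-1)
    adjacent = nxt["beep"] == vf["beep"] + 1
    lag = vf[adjacent]
    lead = nxt[adjacent]
    out = pd.DataFrame(
        {
            "subject_id": lag["subject_id"].to_numpy(),
            "group": lag["group"].to_numpy(),
            "age": lag["age"].to_numpy(),
            "gender": lag["gender"].to_numpy(),
            "day": lag["day"].to_numpy(),
            "beep_from": lag["beep"].to_numpy(),
            "beep_to": lead["beep"].to_numpy().astype(int),
            "X_lag": lag["stress"].to_numpy(),
            "M_lag": lag["negative_affect"].to_numpy(),
            "Y_lag": lag["psychotic_experiences"].to_numpy(),
            "X_t": lead["stress"].to_numpy(),
            "M_t": lead["negative_affect"].to_numpy(),
            "Y_t": lead["psychotic_experiences"].to_numpy(),
        }
    )
    out["group"] = pd.Categorical(out["group"], categories=GROUPS)
    return LaggedDataset(out.reset_index(drop=True), ds.design)


def _empty_lagged_frame() -> pd.DataFrame:
    cols = [
        "subject_id", "group", "age", "gender", "day", "beep_from", "beep_to",
        "X_lag", "M_lag", "Y_lag", "X_t", "M_t", "Y_t",
    ]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
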