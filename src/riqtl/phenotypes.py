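"""Animal-level axon counts to strain summaries, heritability and checks.

The primary phenotype is the number of necrotic axons per optic-nerve
cross-section, estimated from a minimum of 12 evenly spaced counting fields:
density = total field count / sampled area, per-nerve count = density x
nerve cross-section area.  Strain summaries are mean +/- SEM over replicate
animals.

Heritability uses the one-way ANOVA decomposition over strains:
``Ve = MS_within``, ``Va = (MS_between - MS_within) / n0`` (clamped at 0)
with the unbalanced-design coefficient ``n0 = (N - sum(n_i^2)/N) / (k - 1)``.
Two summaries are reported: the conventional intraclass ratio
``h2 = Va / (Va + Ve)`` and the strain-mean version
``h2_RIx = Va / (Va + Ve / n_bar)`` with ``n_bar`` the harmonic mean
replicate count, which credits the variance reduction from averaging
replicates before mapping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._errors import ConfigError, DataError

MIN_FIELDS = 12


@dataclass
class AnimalRecord:
    strain: str
    sex: str = "F"
    age_months: float = float("nan")
    field_counts_live: list[float] | None = None
    field_counts_necrotic: list[float] | None = None
    field_area_um2: float = float("nan")
    nerve_area_um2: float = float("nan")
    necrotic_count: float | None = None   # direct value when field data absent

    def __post_init__(self) -> None:
        if self.field_counts_necrotic is not None:
            if len(self.field_counts_necrotic) < MIN_FIELDS:
                raise DataError(
                    f"{self.strain}: {len(self.field_counts_necrotic)} fields, "
                    f"minimum is {MIN_FIELDS}"
                )
            if min(self.field_counts_necrotic) < 0:
                raise DataError(f"{self.strain}: negative field count")
            if not (self.field_area_um2 > 0 and self.nerve_area_um2 > 0):
                raise DataError(f"{self.strain}: field/nerve areas must be positive")


@dataclass
class HeritabilityResult:
    Va: float
    Ve: float
    n_eff: float            # harmonic-mean replicate count
    h2_conventional: float
    h2_rix: float


def nerve_counts(rec: AnimalRecord) -> tuple[int, float, int]:
    """(necrotic per nerve, necrotic density per um^2, live per nerve).

    density = sum(field counts) / (k * field area); per-nerve count =
    round(density * nerve area), half away from zero.
    """
    if rec.field_counts_necrotic is None:
        raise DataError(f"{rec.strain}: no field-level data")
    k = len(rec.field_counts_necrotic)
    sampled = k * rec.field_area_um2
    if sampled <= 0:
        raise DataError(f"{rec.strain}: zero sampled area")
    dens_necro = float(np.sum(rec.field_counts_necrotic)) / sampled
    necro = int(np.floor(dens_necro * rec.nerve_area_um2 + 0.5))
    live = 0
    if rec.field_counts_live is not None:
        k_live = len(rec.field_counts_live)
        dens_live = float(np.sum(rec.field_counts_live)) / (k_live * rec.field_area_um2)
        live = int(np.floor(dens_live * rec.nerve_area_um2 + 0.5))
    return necro, dens_necro, live


def animal_value(rec: AnimalRecord, value: str = "necrotic") -> float:
    """Scalar trait value for one animal (count or density)."""
    if rec.field_counts_necrotic is not None:
        necro, dens, _ = nerve_counts(rec)
        return float(necro) if value == "necrotic" else dens
    if rec.necrotic_count is None:
        raise DataError(f"{rec.strain}: neither field data nor a direct count")
    return float(rec.necrotic_count)


def animals_to_frame(records: list[AnimalRecord]) -> pd.DataFrame:
    """Flat animal table (one row per animal) for TSV export."""
    rows = []
    for r in records:
        rows.append({
            "strain": r.strain, "sex": r.sex, "age_months": r.age_months,
            "necrotic_count": animal_value(r),
            "field_area_um2": r.field_area_um2, "nerve_area_um2": r.nerve_area_um2,
            "fields_necrotic": ",".join(f"{c:g}" for c in r.field_counts_necrotic)
            if r.field_counts_necrotic is not None else "",
            "fields_live": ",".join(f"{c:g}" for c in r.field_counts_live)
            if r.field_counts_live is not None else "",
        })
    return pd.DataFrame(rows)


def frame_to_animals(df: pd.DataFrame) -> list[AnimalRecord]:
    records = []
    for row in df.itertuples(index=False):
        fn = getattr(row, "fields_necrotic", "") or ""
        fl = getattr(row, "fields_live", "") or ""
        if isinstance(fn, str) and fn:
            records.append(AnimalRecord(
                strain=str(row.strain), sex=str(row.sex), age_months=float(row.age_months),
                field_counts_necrotic=[float(x) for x in fn.split(",")],
                field_counts_live=[float(x) for x in fl.split(",")] if fl else None,
                field_area_um2=float(row.field_area_um2),
                nerve_area_um2=float(row.nerve_area_um2)))
        else:
            records.append(AnimalRecord(strain=str(row.strain), sex=str(row.sex),
                                        age_months=float(row.age_months),
                                        necrotic_count=float(row.necrotic_count)))
    return records


def strain_summary(records: list[AnimalRecord], value: str = "necrotic") -> pd.DataFrame:
    """Per-strain mean, SEM (= sd/sqrt(n), absent at n=1) and replicate count."""
    if not records:
        raise DataError("no animal records")
    df = pd.DataFrame({"strain": [r.strain for r in records],
                       "v": [animal_value(r, value) for r in records]})
    grp = df.groupby("strain", sort=True)["v"]
    out = pd.DataFrame({
        "value": grp.mean(),
        "se": grp.std(ddof=1) / np.sqrt(grp.count()),
        "n": grp.count().astype(float),
    })
    out.loc[out["n"] == 1, "se"] = np.nan
    out.index.name = "strain"
    return out


# ---------------------------------------------------------------------------
# winsorization / outliers
# ---------------------------------------------------------------------------

def winsorize(strain_means: pd.DataFrame, high_outliers: list[str],
              low_outliers: list[str]) -> pd.DataFrame:
    """Rank-preserving nearest-value replacement of flagged extremes.

    The k flagged high values become max(retained)+1, +2, ..., +k in
    ascending raw order; flagged low values become min(retained)-1, -2, ...
    in descending raw order.  All other values are untouched, so the rank
    order of every strain is preserved.
    """
    overlap = set(high_outliers) & set(low_outliers)
    if overlap:
        raise ConfigError(f"outlier sets overlap: {sorted(overlap)}")
    for s in list(high_outliers) + list(low_outliers):
        if s not in strain_means.index:
            raise ConfigError(f"unknown outlier strain {s!r}")
    flagged = set(high_outliers) | set(low_outliers)
    retained = strain_means.loc[~strain_means.index.isin(flagged), "value"]
    if retained.empty:
        raise ConfigError("no retained values after flagging outliers")
    out = strain_means.copy()
    hi_sorted = sorted(high_outliers, key=lambda s: strain_means.loc[s, "value"])
    for step, s in enumerate(hi_sorted, start=1):
        out.loc[s, "value"] = retained.max() + step
    lo_sorted = sorted(low_outliers, key=lambda s: -strain_means.loc[s, "value"])
    for step, s in enumerate(lo_sorted, start=1):
        out.loc[s, "value"] = retained.min() - step
    return out


def detect_outliers(strain_means: pd.DataFrame, k_iqr: float = 1.5
                    ) -> tuple[list[str], list[str]]:
    """Tukey-fence outlier labels outside [Q1 - k IQR, Q3 + k IQR]."""
    v = strain_means["value"]
    if len(v) < 4:
        raise DataError("need at least 4 strains for fence-based detection")
    q1, q3 = v.quantile(0.25), v.quantile(0.75)
    iqr = q3 - q1
    high = list(v.index[v > q3 + k_iqr * iqr])
    low = list(v.index[v < q1 - k_iqr * iqr])
    return high, low


# ---------------------------------------------------------------------------
# heritability
# ---------------------------------------------------------------------------

def heritability(data: list[AnimalRecord] | pd.DataFrame,
                 value: str = "necrotic") -> HeritabilityResult:
    """Variance components by one-way ANOVA over strains.

    Accepts either animal records (replicate-level path) or a strain summary
    with ``value, se, n`` columns, in which case within-strain variance is
    reconstructed as ``n_i * se_i^2``.
    """
    if isinstance(data, pd.DataFrame):
        sub = data.dropna(subset=["n"]).copy()
        if len(sub) < 2 or not (sub["n"] > 1).any():
            raise DataError("heritability undefined: need >= 2 strains, some replicated")
        means = sub["value"].to_numpy(float)
        ns = sub["n"].to_numpy(float)
        # reconstruct within-strain sample variances; unreplicated strains
        # contribute zero within sum of squares (zero df)
        s2 = np.where(ns > 1, ns * np.nan_to_num(sub["se"].to_numpy(float)) ** 2, 0.0)
        N, k = ns.sum(), len(ns)
        grand = float((means * ns).sum() / N)
        ss_between = float((ns * (means - grand) ** 2).sum())
        ss_within = float(((ns - 1) * s2).sum())
    else:
        df = pd.DataFrame({"strain": [r.strain for r in data],
                           "v": [animal_value(r, value) for r in data]})
        if df["strain"].nunique() < 2 or len(df) == df["strain"].nunique():
            raise DataError("heritability undefined: need >= 2 strains, some replicated")
        grp = df.groupby("strain")["v"]
        ns = grp.count().to_numpy(float)
        means = grp.mean().to_numpy(float)
        N, k = ns.sum(), len(ns)
        grand = float(df["v"].mean())
        ss_between = float((ns * (means - grand) ** 2).sum())
        ss_within = float(((df["v"] - df.groupby("strain")["v"].transform("mean")) ** 2).sum())
    ms_between = ss_between / (k - 1)
    ms_within = ss_within / (N - k)
    n0 = (N - (ns ** 2).sum() / N) / (k - 1)
    Ve = ms_within
    Va = max((ms_between - ms_within) / n0, 0.0)
    n_bar = len(ns) / (1.0 / ns).sum()               # harmonic mean
    h2_conv = Va / (Va + Ve) if Va + Ve > 0 else 0.0
    h2_rix = Va / (Va + Ve / n_bar) if Va + Ve / n_bar > 0 else 0.0
    return HeritabilityResult(Va=Va, Ve=Ve, n_eff=float(n_bar),
                              h2_conventional=float(h2_conv), h2_rix=float(h2_rix))


# ---------------------------------------------------------------------------
# sex and age checks
# ---------------------------------------------------------------------------

def age_regression(records: list[AnimalRecord], log_age: bool = False,
                   value: str = "necrotic") -> tuple[float, float]:
    """OLS slope of the count on (age - 13) months (or log age) and R^2."""
    ages = np.array([r.age_months for r in records], float)
    if len(records) < 3:
        raise DataError("need >= 3 records for the age regression")
    if np.ptp(ages) == 0:
        raise DataError("constant age: slope undefined")
    y = np.array([animal_value(r, value) for r in records], float)
    if np.ptp(y) == 0:
        return 0.0, 0.0
    x = np.log(ages) if log_age else ages - 13.0
    res = stats.linregress(x, y)
    return float(res.slope), float(res.rvalue ** 2)


def sex_compare(records: list[AnimalRecord], paired_by_strain: bool = False,
                value: str = "necrotic") -> tuple[float, float, float]:
    """Welch two-sample t-test male vs female -> (mean_M, mean_F, p).

    Unpaired mode compares animal values; the paired-by-strain mode compares
    within-strain sex means restricted to strains with >= 2 animals of each
    sex.
    """
    df = pd.DataFrame({"strain": [r.strain for r in records],
                       "sex": [r.sex for r in records],
                       "v": [animal_value(r, value) for r in records]})
    if paired_by_strain:
        counts = df.groupby(["strain", "sex"])["v"].count().unstack(fill_value=0)
        ok = counts.index[(counts.get("M", 0) >= 2) & (counts.get("F", 0) >= 2)]
        df = df[df["strain"].isin(ok)]
        if df.empty:
            raise DataError("no strains with >= 2 animals of both sexes")
        df = df.groupby(["strain", "sex"])["v"].mean().reset_index()
    m = df.loc[df["sex"] == "M", "v"].to_numpy(float)
    f = df.loc[df["sex"] == "F", "v"].to_numpy(float)
    if len(m) == 0 or len(f) == 0:
        raise DataError("both sexes must be represented")
    if np.array_equal(np.sort(m), np.sort(f)):
        return float(m.mean()), float(f.mean()), 1.0
    t = stats.ttest_ind(m, f, equal_var=False)
    return float(m.mean()), float(f.mean()), float(t.pvalue)
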