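"""Genome scans for RI strain means.

Two engines on the GeneNetwork LRS scale (LOD = LRS / (2 ln 10)):

* Haley-Knott regression: least squares of strain means on expected D-allele
  dosage (0/2 coding, so the slope is the per-allele effect) at typed markers
  and pseudomarkers.  LRS = n * ln(RSS0 / RSS1) against the intercept-only
  model.  Genome-wide thresholds come from permuting strain means
  (significant: genome-wide p = 0.05; suggestive: p = 0.63, one false
  positive per genome expected); localization from bootstrap resampling of
  strains and a LOD-drop support interval.

* A GEMMA-style linear mixed model y = mu + x b + u + e with
  u ~ N(0, sg^2 K), kinship K = Z Z'/p over MAF-filtered centered dosages,
  leave-one-chromosome-out by default.  The variance ratio lambda = sg^2/se^2
  is profiled out by bounded scalar search on log10(lambda) in [-5, 5],
  re-optimized under both null and alternative, and the per-marker LRS is
  the likelihood ratio 2(l1 - l0).

Between typed markers the expected dosage conditions on both flanks through
a two-state Markov step whose switch probability is the sib-mated
RI-expanded recombinant fraction R(d) = 4r/(1+6r) with Haldane r.
Heterozygous/unknown calls are missing (dropped position-wise in HK,
mean-imputed in kinship and LMM marker vectors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import eigh, solve
from scipy.optimize import minimize_scalar

from ._errors import ConfigError, DataError
from .io_formats import LRS_PER_LOD, GenotypeMatrix
from .simulate import ri_recomb_fraction


@dataclass
class QTLScan:
    positions: pd.DataFrame       # chromosome, cM, Mb (sorted by map position)
    lrs: np.ndarray
    additive: np.ndarray          # effect per D-allele substitution
    method: str = "HK"

    def __post_init__(self) -> None:
        self.lrs = np.asarray(self.lrs, float)
        self.additive = np.asarray(self.additive, float)

    @property
    def lod(self) -> np.ndarray:
        return self.lrs / LRS_PER_LOD

    def peak_index(self) -> int:
        """Argmax of LRS; ties break to the lowest genomic coordinate."""
        return int(np.argmax(self.lrs))

    def peak(self) -> pd.Series:
        i = self.peak_index()
        row = self.positions.iloc[i]
        return pd.Series({"chromosome": row["chromosome"], "cM": row["cM"],
                          "Mb": row["Mb"], "lrs": self.lrs[i],
                          "lod": self.lod[i], "additive": self.additive[i]})

    def to_frame(self) -> pd.DataFrame:
        df = self.positions.copy()
        df["LRS"] = self.lrs
        df["LOD"] = self.lod
        df["additive"] = self.additive
        df["method"] = self.method
        return df


@dataclass
class Thresholds:
    significant_lrs: float        # genome-wide alpha = 0.05
    suggestive_lrs: float         # genome-wide alpha = 0.63
    n_perm: int
    seed: int


@dataclass
class KinshipMatrix:
    matrix: np.ndarray
    strains: list[str]
    excluded_chromosome: str | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.matrix, float)
        if not np.allclose(K, K.T, atol=1e-10):
            raise DataError("kinship matrix not symmetric")
        w = np.linalg.eigvalsh(K)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise DataError("kinship matrix not positive semi-definite")
        self.matrix = K


@dataclass
class LmmFit:
    lam: float                    # variance ratio sg^2 / se^2
    beta: float
    loglik: float


# ---------------------------------------------------------------------------
# expected dosage
# ---------------------------------------------------------------------------

def _conditional_dosage(gl: np.ndarray, gr: np.ndarray,
                        rho_l: float, rho_r: float) -> np.ndarray:
    """Expected 0/2 dosage given flanking genotypes and switch probabilities.

    A missing flank contributes a flat factor; both flanks missing -> NaN.
    """
    fl_D = np.where(np.isnan(gl), 1.0, np.where(gl == 2.0, 1.0 - rho_l, rho_l))
    fr_D = np.where(np.isnan(gr), 1.0, np.where(gr == 2.0, 1.0 - rho_r, rho_r))
    fl_B = np.where(np.isnan(gl), 1.0, np.where(gl == 0.0, 1.0 - rho_l, rho_l))
    fr_B = np.where(np.isnan(gr), 1.0, np.where(gr == 0.0, 1.0 - rho_r, rho_r))
    pD = fl_D * fr_D
    pB = fl_B * fr_B
    out = 2.0 * pD / (pD + pB)
    out[np.isnan(gl) & np.isnan(gr)] = np.nan
    return out


def dosage(g: GenotypeMatrix, chromosome: str, cM: float) -> np.ndarray:
    """Per-strain expected D-allele dosage at an arbitrary map position."""
    sub = g.markers[g.markers["chromosome"] == str(chromosome)]
    if sub.empty:
        raise DataError(f"chromosome {chromosome!r} not on the map")
    cms = sub["cM"].to_numpy()
    if cM < cms[0] - 1e-9 or cM > cms[-1] + 1e-9:
        raise DataError(f"position {cM} cM off the map of chromosome {chromosome!r}")
    dos = g.dosage_matrix()[sub.index.to_numpy()]
    exact = np.where(np.isclose(cms, cM))[0]
    if len(exact):
        return dos[exact[0]]
    right = int(np.searchsorted(cms, cM))
    left = right - 1
    return _conditional_dosage(dos[left], dos[right],
                               float(ri_recomb_fraction(cM - cms[left])),
                               float(ri_recomb_fraction(cms[right] - cM)))


def scan_grid(g: GenotypeMatrix, step_cM: float | None = 1.0
              ) -> tuple[pd.DataFrame, np.ndarray]:
    """Scan positions (typed markers plus a step_cM pseudomarker lattice)
    and the (positions x strains) expected-dosage matrix."""
    pos_rows: list[tuple[str, float, float]] = []
    blocks: list[np.ndarray] = []
    full_dos = g.dosage_matrix()
    for chrom, grp in g.markers.groupby("chromosome", sort=False):
        cms = grp["cM"].to_numpy()
        mbs = grp["Mb"].to_numpy()
        dos = full_dos[grp.index.to_numpy()]
        if step_cM is None:
            grid = cms
        else:
            lattice = np.arange(cms[0], cms[-1] + 1e-9, step_cM)
            grid = np.unique(np.concatenate([cms, lattice]))
        block = np.empty((len(grid), g.n_strains))
        for k, p in enumerate(grid):
            j = int(np.searchsorted(cms, p))
            if j < len(cms) and np.isclose(cms[j], p):
                block[k] = dos[j]
                mb = mbs[j]
            else:
                left, right = j - 1, j
                block[k] = _conditional_dosage(
                    dos[left], dos[right],
                    float(ri_recomb_fraction(p - cms[left])),
                    float(ri_recomb_fraction(cms[right] - p)))
                frac = (p - cms[left]) / (cms[right] - cms[left])
                mb = mbs[left] + frac * (mbs[right] - mbs[left])
            pos_rows.append((str(chrom), float(p), float(mb)))
        blocks.append(block)
    positions = pd.DataFrame(pos_rows, columns=["chromosome", "cM", "Mb"])
    return positions, np.vstack(blocks)


# ---------------------------------------------------------------------------
# Haley-Knott
# ---------------------------------------------------------------------------

def _align(g: GenotypeMatrix, trait: pd.DataFrame,
           min_shared: int = 10) -> tuple[list[str], np.ndarray]:
    shared = [s for s in g.strains if s in trait.index]
    if len(shared) < min_shared:
        raise DataError(f"only {len(shared)} strains shared between genotypes and trait "
                        f"(need >= {min_shared})")
    return shared, trait.loc[shared, "value"].to_numpy(float)


def _ols_lrs(D: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-row LRS = n ln(RSS0/RSS1) and slope for complete-case rows of D."""
    P, n = D.shape
    lrs = np.zeros(P)
    beta = np.zeros(P)
    nan_rows = np.isnan(D).any(axis=1)
    if (~nan_rows).any():
        Dc = D[~nan_rows] - D[~nan_rows].mean(axis=1, keepdims=True)
        yc = y - y.mean()
        syy = float(yc @ yc)
        sxy = Dc @ yc
        sxx = np.einsum("ij,ij->i", Dc, Dc)
        ok = (sxx > 1e-12) & (syy > 0)
        r2 = np.zeros(len(sxx))
        r2[ok] = sxy[ok] ** 2 / (sxx[ok] * syy)
        r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
        lrs[~nan_rows] = -n * np.log1p(-r2)
        beta[~nan_rows] = np.where(ok, sxy / np.where(sxx > 1e-12, sxx, 1.0), 0.0)
    for i in np.where(nan_rows)[0]:
        m = ~np.isnan(D[i])
        if m.sum() < 3:
            continue
        x, yy = D[i, m], y[m]
        xc, yyc = x - x.mean(), yy - yy.mean()
        sxx, syy = float(xc @ xc), float(yyc @ yyc)
        if sxx <= 1e-12 or syy <= 0:
            continue
        r2 = min((float(xc @ yyc) ** 2) / (sxx * syy), 1.0 - 1e-15)
        lrs[i] = -m.sum() * np.log1p(-r2)
        beta[i] = float(xc @ yyc) / sxx
    return lrs, beta


def hk_scan(g: GenotypeMatrix, trait: pd.DataFrame,
            step_cM: float | None = 1.0) -> QTLScan:
    """Haley-Knott regression of unweighted strain means on expected dosage."""
    shared, y = _align(g, trait)
    gs = g.subset_strains(shared)
    positions, D = scan_grid(gs, step_cM)
    lrs, beta = _ols_lrs(D, y)
    if lrs.max() == 0.0:
        warnings.warn("no variable position: all-zero scan", stacklevel=2)
    return QTLScan(positions=positions, lrs=lrs, additive=beta, method="HK")


def permutation_thresholds(g: GenotypeMatrix, trait: pd.DataFrame,
                           n_perm: int = 2000, seed: int = 0,
                           step_cM: float | None = 1.0) -> Thresholds:
    """Empirical genome-wide max-LRS quantiles under strain-label permutation."""
    if n_perm < 100:
        raise ConfigError("n_perm must be >= 100")
    shared, y = _align(g, trait)
    gs = g.subset_strains(shared)
    _, D = scan_grid(gs, step_cM)
    rng = np.random.default_rng(seed)
    maxes = _perm_max_lrs(D, y, n_perm, rng)
    return Thresholds(significant_lrs=float(np.quantile(maxes, 0.95)),
                      suggestive_lrs=float(np.quantile(maxes, 1.0 - 0.63)),
                      n_perm=n_perm, seed=seed)


def _perm_max_lrs(D: np.ndarray, y: np.ndarray, n_perm: int,
                  rng: np.random.Generator) -> np.ndarray:
    n = len(y)
    if np.isnan(D).any():
        maxes = np.empty(n_perm)
        for b in range(n_perm):
            lrs, _ = _ols_lrs(D, y[rng.permutation(n)])
            maxes[b] = lrs.max()
        return maxes
    Dc = D - D.mean(axis=1, keepdims=True)
    sxx = np.einsum("ij,ij->i", Dc, Dc)
    keep = sxx > 1e-12
    Dc, sxx = Dc[keep], sxx[keep]
    if Dc.shape[0] == 0:
        return np.zeros(n_perm)
    Y = np.empty((n, n_perm))
    for b in range(n_perm):
        Y[:, b] = y[rng.permutation(n)]
    Yc = Y - Y.mean(axis=0, keepdims=True)
    syy = float(((y - y.mean()) ** 2).sum())
    if syy <= 0:
        return np.zeros(n_perm)
    r2 = (Dc @ Yc) ** 2 / (sxx[:, None] * syy)
    r2 = np.clip(r2, 0.0, 1.0 - 1e-15)
    return (-n * np.log1p(-r2)).max(axis=0)


def bootstrap_peak(g: GenotypeMatrix, trait: pd.DataFrame, n_boot: int = 2000,
                   seed: int = 0, step_cM: float | None = 1.0) -> pd.DataFrame:
    """Peak-position frequency under strain resampling with replacement."""
    if n_boot < 100:
        raise ConfigError("n_boot must be >= 100")
    shared, y = _align(g, trait)
    gs = g.subset_strains(shared)
    positions, D = scan_grid(gs, step_cM)
    rng = np.random.default_rng(seed)
    counts = np.zeros(len(positions))
    n = len(y)
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        lrs, _ = _ols_lrs(D[:, idx], y[idx])
        counts[int(np.argmax(lrs))] += 1
    out = positions.copy()
    out["frequency"] = counts / n_boot
    return out


def support_interval(scan: QTLScan, drop_lod: float = 1.5
                     ) -> tuple[str, float, float]:
    """LOD-drop support interval around the genome-wide peak."""
    if scan.lrs.max() <= 0:
        raise DataError("flat scan: no support interval")
    i = scan.peak_index()
    chrom = scan.positions["chromosome"].iloc[i]
    on = np.where(scan.positions["chromosome"].to_numpy() == chrom)[0]
    lod = scan.lod
    cutoff = lod[i] - drop_lod
    lo = hi = i
    j = int(np.where(on == i)[0][0])
    k = j
    while k - 1 >= 0 and lod[on[k - 1]] >= cutoff:
        k -= 1
    lo = on[k]
    k = j
    while k + 1 < len(on) and lod[on[k + 1]] >= cutoff:
        k += 1
    hi = on[k]
    return (str(chrom), float(scan.positions["Mb"].iloc[lo]),
            float(scan.positions["Mb"].iloc[hi]))


# ---------------------------------------------------------------------------
# kinship + LMM
# ---------------------------------------------------------------------------

def kinship(g: GenotypeMatrix, loco_chromosome: str | None = None,
            maf_min: float = 0.05) -> KinshipMatrix:
    """K = Z Z'/p over column-centered 0/2 dosages of MAF-passing markers."""
    keep = g.maf() > maf_min
    if loco_chromosome is not None:
        keep &= (g.markers["chromosome"].to_numpy() != str(loco_chromosome))
    if keep.sum() < 2:
        raise DataError("fewer than 2 markers survive MAF/LOCO filtering")
    Z = g.dosage_matrix()[keep].T                     # strains x markers
    col_mean = np.nanmean(Z, axis=0)
    nan_idx = np.where(np.isnan(Z))
    Z[nan_idx] = col_mean[nan_idx[1]]
    Z = Z - Z.mean(axis=0, keepdims=True)
    K = Z @ Z.T / Z.shape[1]
    return KinshipMatrix(matrix=K, strains=list(g.strains),
                         excluded_chromosome=loco_chromosome)


def _profile_loglik(lam: float, s: np.ndarray, yr: np.ndarray,
                    Xr: np.ndarray) -> tuple[float, np.ndarray]:
    """ML log-likelihood profiled over beta and se^2 at fixed lambda."""
    w = 1.0 / (lam * s + 1.0)
    A = (Xr.T * w) @ Xr
    b = (Xr.T * w) @ yr
    beta = solve(A, b, assume_a="pos")
    resid = yr - Xr @ beta
    rss = float((w * resid ** 2).sum())
    n = len(yr)
    ll = -0.5 * (n * np.log(2.0 * np.pi * rss / n) + np.log(lam * s + 1.0).sum() + n)
    return ll, beta


def _fit_lmm(s: np.ndarray, yr: np.ndarray, Xr: np.ndarray) -> LmmFit:
    """Optimize lambda on log10 scale in [-5, 5] (bounded scalar search)."""
    res = minimize_scalar(lambda lg: -_profile_loglik(10.0 ** lg, s, yr, Xr)[0],
                          bounds=(-5.0, 5.0), method="bounded",
                          options={"xatol": 1e-7})
    lam = float(10.0 ** res.x)
    ll, beta = _profile_loglik(lam, s, yr, Xr)
    return LmmFit(lam=lam, beta=float(beta[-1]), loglik=ll)


def lmm_scan(g: GenotypeMatrix, trait: pd.DataFrame, loco: bool = True,
             maf_min: float = 0.05,
             kinship_override: KinshipMatrix | None = None) -> QTLScan:
    """Mixed-model association at typed markers, LRS = 2(l1 - l0).

    ``kinship_override`` fixes one kinship matrix for every chromosome
    (used for oracle checks, e.g. K = I collapses the model to OLS).
    """
    shared, y = _align(g, trait)
    gs = g.subset_strains(shared)
    maf = gs.maf()
    dos = gs.dosage_matrix()
    n = len(y)
    lrs = np.zeros(gs.n_markers)
    beta = np.zeros(gs.n_markers)
    tested = np.zeros(gs.n_markers, bool)
    ones = np.ones((n, 1))
    for chrom in pd.unique(gs.markers["chromosome"]):
        on = np.where(gs.markers["chromosome"].to_numpy() == chrom)[0]
        test = on[maf[on] > maf_min]
        if len(test) == 0:
            continue
        if kinship_override is not None:
            K = kinship_override.matrix
        else:
            K = kinship(gs, loco_chromosome=str(chrom) if loco else None,
                        maf_min=maf_min).matrix
        s, U = eigh(K)
        s = np.clip(s, 0.0, None)
        yr = U.T @ y
        X0r = U.T @ ones
        ll0 = _fit_lmm(s, yr, X0r).loglik
        for i in test:
            x = dos[i].copy()
            bad = np.isnan(x)
            if bad.any():
                x[bad] = x[~bad].mean()
            Xr = U.T @ np.column_stack([np.ones(n), x])
            fit = _fit_lmm(s, yr, Xr)
            lrs[i] = max(2.0 * (fit.loglik - ll0), 0.0)
            beta[i] = fit.beta
            tested[i] = True
    positions = gs.markers[["chromosome", "cM", "Mb"]].reset_index(drop=True)
    return QTLScan(positions=positions[tested].reset_index(drop=True),
                   lrs=lrs[tested], additive=beta[tested], method="LMM")


# ---------------------------------------------------------------------------
# robustness scenarios
# ---------------------------------------------------------------------------

def robustness_suite(g: GenotypeMatrix, trait_raw: pd.DataFrame,
                     high_outliers: list[str], low_outliers: list[str],
                     step_cM: float | None = 1.0) -> pd.DataFrame:
    """Peak summary under raw / winsorized / censored outlier handling."""
    from .phenotypes import winsorize

    flagged = list(high_outliers) + list(low_outliers)
    scenarios = {
        "raw": trait_raw,
        "winsorized": winsorize(trait_raw, high_outliers, low_outliers),
        "censored": trait_raw.drop(index=flagged),
    }
    rows = []
    for name, trait in scenarios.items():
        scan = hk_scan(g, trait, step_cM)
        pk = scan.peak()
        rows.append({"scenario": name, "n_strains": len(trait),
                     "chromosome": pk["chromosome"], "cM": pk["cM"],
                     "Mb": pk["Mb"], "lrs": pk["lrs"], "additive": pk["additive"]})
    return pd.DataFrame(rows)
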