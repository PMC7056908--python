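"""Readers and writers for the file dialects the pipeline touches.

Genotypes use the GeneNetwork ``.geno`` dialect: ``@``-prefixed header
declarations mapping the file's allele letters onto maternal (B), paternal
(D), heterozygous (H) and unknown (U) codes, followed by a column row
``Chr  Locus  cM  Mb  <strain...>`` and one tab-separated line per marker.
Trait tables, expression matrices, annotation tables and genome scans are
plain TSV. Every reader/writer pair round-trips bit-identically on files the
writer produced (the writer defines the canonical form: tab separation,
markers sorted by map position).

Physical positions are megabases (1-based, floating), genetic positions
centimorgans; chromosome labels are text ("12", "X").
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._errors import DataError, FormatError

GENO_CODES = ("B", "D", "H", "U")

#: LOD = LRS / (2 ln 10)
LRS_PER_LOD = 2.0 * np.log(10.0)


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Strains x markers of biallelic parental codes plus the marker map.

    ``markers`` is a DataFrame with columns ``marker_id, chromosome, cM, Mb``
    (one row per marker, positions strictly increasing within a chromosome);
    ``calls`` is a (n_markers, n_strains) array over the alphabet B/D/H/U.
    """

    strains: list[str]
    markers: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="<U1")
        if self.calls.shape != (len(self.markers), len(self.strains)):
            raise DataError(
                f"genotype calls shape {self.calls.shape} does not match "
                f"{len(self.markers)} markers x {len(self.strains)} strains"
            )
        bad = ~np.isin(self.calls, GENO_CODES)
        if bad.any():
            i = int(np.argwhere(bad)[0, 0])
            mid = self.markers["marker_id"].iloc[i]
            raise DataError(f"unknown genotype code at marker {mid!r}")
        if self.markers["marker_id"].duplicated().any():
            dup = self.markers["marker_id"][self.markers["marker_id"].duplicated()].iloc[0]
            raise DataError(f"duplicate marker id {dup!r}")
        for _, grp in self.markers.groupby("chromosome", sort=False):
            for col in ("cM", "Mb"):
                v = grp[col].to_numpy(float)
                if len(v) > 1 and not (np.diff(v) > 0).all():
                    raise DataError(
                        f"marker {col} positions not strictly increasing on "
                        f"chromosome {grp['chromosome'].iloc[0]!r}"
                    )

    @property
    def n_strains(self) -> int:
        return len(self.strains)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def dosage_matrix(self) -> np.ndarray:
        """0/2 dosage of the D allele per (marker, strain); H/U -> NaN.

        RI strains are nominally homozygous, so heterozygous calls are
        treated as missing rather than coded 1.
        """
        d = np.full(self.calls.shape, np.nan)
        d[self.calls == "B"] = 0.0
        d[self.calls == "D"] = 2.0
        return d

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing homozygous calls."""
        b = (self.calls == "B").sum(axis=1).astype(float)
        d = (self.calls == "D").sum(axis=1).astype(float)
        tot = b + d
        with np.errstate(invalid="ignore"):
            f = np.where(tot > 0, d / np.where(tot > 0, tot, 1.0), np.nan)
        return np.minimum(f, 1.0 - f)

    def subset_strains(self, strains: list[str]) -> "GenotypeMatrix":
        idx = [self.strains.index(s) for s in strains]
        return GenotypeMatrix(list(strains), self.markers.reset_index(drop=True),
                              self.calls[:, idx])


@dataclass
class ExpressionDataset:
    """Probes x strains log2 abundances with probe-level annotation.

    ``probes`` columns: ``probe_id, gene_id, snp_overlap, annotated``;
    unresolvable probes are retained with ``annotated=False``.
    """

    probes: pd.DataFrame
    strains: list[str]
    values: np.ndarray
    tissue: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probes), len(self.strains)):
            raise DataError("expression values shape does not match probes x strains")

    def probe_values(self, probe_id: str) -> np.ndarray:
        idx = self.probes.index[self.probes["probe_id"] == probe_id]
        if len(idx) == 0:
            raise DataError(f"unknown probe {probe_id!r}")
        return self.values[idx[0]]


@dataclass
class AnnotationTables:
    """Gene / probe / variant / GO annotation, cross-referenced by gene_id."""

    genes: pd.DataFrame        # gene_id, symbol, chromosome, position_Mb
    probes: pd.DataFrame       # probe_id, gene_id, snp_overlap
    variants: pd.DataFrame     # gene_id, class
    go_terms: pd.DataFrame     # term_id, name, parents (list), genes (list)

    def __post_init__(self) -> None:
        known = set(self.genes["gene_id"])
        for name, tab in (("probes", self.probes), ("variants", self.variants)):
            if len(tab):
                missing = set(tab["gene_id"]) - known
                if missing:
                    raise DataError(f"{name} reference unknown gene_ids: {sorted(missing)[:5]}")
        _check_go_acyclic(self.go_terms)


def _check_go_acyclic(go: pd.DataFrame) -> None:
    parents = {t: list(p) for t, p in zip(go["term_id"], go["parents"])}
    state: dict[str, int] = {}

    def visit(t: str) -> None:
        state[t] = 1
        for p in parents.get(t, ()):  # edge child -> parent
            s = state.get(p, 0)
            if s == 1:
                raise DataError(f"GO parent links contain a cycle through {t!r}")
            if s == 0:
                visit(p)
        state[t] = 2

    for t in parents:
        if state.get(t, 0) == 0:
            visit(t)


# ---------------------------------------------------------------------------
# .geno
# ---------------------------------------------------------------------------

def read_geno(path) -> GenotypeMatrix:
    """Parse a GeneNetwork-style .geno file.

    Lines beginning ``#`` are comments; ``@key:value`` lines declare the code
    mapping (at least @mat/@pat, optionally @het/@unk); the first non-@ line
    is the column header ``Chr Locus cM Mb strain1 ...``.
    """
    decl: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[str]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            if line.startswith("@"):
                if ":" not in line:
                    raise FormatError(f"line {lineno}: malformed declaration {line!r}")
                key, val = line[1:].split(":", 1)
                decl[key.strip().lower()] = val.strip()
                continue
            fields = line.split("\t")
            if header is None:
                if fields[:4] != ["Chr", "Locus", "cM", "Mb"]:
                    raise FormatError(
                        f"line {lineno}: expected column header 'Chr\\tLocus\\tcM\\tMb\\t...', "
                        f"got {line!r}"
                    )
                header = fields
                continue
            rows.append(fields)
    if header is None:
        raise FormatError("no column header line found")
    for code_key in ("mat", "pat"):
        if code_key not in decl:
            raise FormatError(f"header missing @{code_key} declaration")
    code_map = {
        decl["mat"]: "B",
        decl["pat"]: "D",
        decl.get("het", "H"): "H",
        decl.get("unk", "U"): "U",
    }
    strains = header[4:]
    if not strains:
        raise FormatError("no strain columns declared")
    marker_rows, calls = [], []
    for fields in rows:
        if len(fields) != 4 + len(strains):
            raise FormatError(f"marker line has {len(fields)} fields, expected {4 + len(strains)}")
        chrom, locus, cm, mb = fields[:4]
        try:
            cm_f, mb_f = float(cm), float(mb)
        except ValueError as exc:
            raise FormatError(f"non-numeric position for marker {locus!r}") from exc
        row = []
        for s, call in zip(strains, fields[4:]):
            if call not in code_map:
                raise DataError(f"unknown call {call!r} at marker {locus!r} (strain {s})")
            row.append(code_map[call])
        marker_rows.append((locus, chrom, cm_f, mb_f))
        calls.append(row)
    markers = pd.DataFrame(marker_rows, columns=["marker_id", "chromosome", "cM", "Mb"])
    # canonical order before validation so input row order is irrelevant
    chrom_rank = {c: i for i, c in enumerate(pd.unique(markers["chromosome"]))}
    order = np.lexsort((markers["cM"].to_numpy(),
                        markers["chromosome"].map(chrom_rank).to_numpy()))
    markers = markers.iloc[order].reset_index(drop=True)
    calls_arr = np.array(calls, dtype="<U1")[order]
    return GenotypeMatrix(strains, markers, calls_arr)


def _canonical_marker_order(g: GenotypeMatrix) -> GenotypeMatrix:
    """Sort markers by (chromosome first-appearance, cM); strain order untouched."""
    chrom_rank = {c: i for i, c in enumerate(pd.unique(g.markers["chromosome"]))}
    order = np.lexsort((g.markers["cM"].to_numpy(),
                        g.markers["chromosome"].map(chrom_rank).to_numpy()))
    return GenotypeMatrix(g.strains, g.markers.iloc[order].reset_index(drop=True),
                          g.calls[order])


def write_geno(g: GenotypeMatrix, path, name: str = "riqtl") -> None:
    if not g.strains:
        raise FormatError("cannot write a .geno file with no strains")
    g = _canonical_marker_order(g)
    buf = io.StringIO()
    buf.write(f"@name:{name}\n@type:riset\n@mat:B\n@pat:D\n@het:H\n@unk:U\n")
    buf.write("\t".join(["Chr", "Locus", "cM", "Mb", *g.strains]) + "\n")
    for i, row in enumerate(g.markers.itertuples(index=False)):
        buf.write("\t".join([str(row.chromosome), str(row.marker_id),
                             format(row.cM, "g"), format(row.Mb, "g"),
                             *g.calls[i]]) + "\n")
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def read_trait_table(path) -> pd.DataFrame:
    """Read a GeneNetwork-style trait export (Strain, Value[, SE][, N]).

    Returns a DataFrame indexed by strain with columns ``value, se, n``;
    absent SE/N columns come back as NaN (flagged unavailable).
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    cols = {c.lower(): c for c in df.columns}
    if "strain" not in cols or "value" not in cols:
        raise FormatError("trait table must have Strain and Value columns")
    out = pd.DataFrame({"strain": df[cols["strain"]].astype(str)})
    for field_name, col in (("value", "value"), ("se", "se"), ("n", "n")):
        if col in cols:
            vals = pd.to_numeric(df[cols[col]], errors="coerce")
            raw = df[cols[col]]
            bad = vals.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
            if bad.any():
                raise DataError(
                    f"non-numeric {field_name} for strain {out['strain'][bad].iloc[0]!r}"
                )
            out[field_name] = vals.astype(float)
        else:
            out[field_name] = np.nan
    if out["value"].isna().any():
        raise DataError(f"missing value for strain {out['strain'][out['value'].isna()].iloc[0]!r}")
    if out["strain"].duplicated().any():
        dup = out["strain"][out["strain"].duplicated()].iloc[0]
        raise DataError(f"duplicate strain {dup!r} in trait table")
    return out.set_index("strain")


def write_trait_table(trait: pd.DataFrame, path) -> None:
    df = trait.reset_index()
    df.columns = ["Strain", "Value", "SE", "N"][: len(df.columns)]
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


# ---------------------------------------------------------------------------
# expression + annotation
# ---------------------------------------------------------------------------

def read_expression_matrix(path, annotations: AnnotationTables | None = None,
                           strain_order: list[str] | None = None,
                           tissue: str = "") -> ExpressionDataset:
    """Read a probes x strains TSV (first column ProbeID) of log2 values."""
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    probe_ids = df.iloc[:, 0].astype(str)
    strains = [str(c) for c in df.columns[1:]]
    if strain_order is not None:
        shared = [s for s in strain_order if s in strains]
        if not shared:
            raise DataError("no overlapping strains between expression file and strain order")
        df = df[[df.columns[0], *shared]]
        strains = shared
    values = df.iloc[:, 1:].to_numpy(float)
    if annotations is not None:
        ann = annotations.probes.set_index("probe_id")
        gene_id = probe_ids.map(ann["gene_id"])
        snp = probe_ids.map(ann["snp_overlap"])
        probes = pd.DataFrame({
            "probe_id": probe_ids,
            "gene_id": gene_id,
            "snp_overlap": snp.astype(object),
            "annotated": gene_id.notna(),
        }).reset_index(drop=True)
    else:
        probes = pd.DataFrame({"probe_id": probe_ids, "gene_id": pd.NA,
                               "snp_overlap": pd.NA, "annotated": False})
    return ExpressionDataset(probes, strains, values, tissue=tissue)


def write_expression_matrix(expr: ExpressionDataset, path) -> None:
    df = pd.DataFrame(expr.values, columns=expr.strains)
    df.insert(0, "ProbeID", expr.probes["probe_id"].to_numpy())
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_annotations(genes_path, probes_path, variants_path, go_path) -> AnnotationTables:
    genes = pd.read_csv(genes_path, sep="\t",
                        dtype={"gene_id": str, "symbol": str, "chromosome": str})
    probes = pd.read_csv(probes_path, sep="\t", dtype={"probe_id": str, "gene_id": str})
    probes["snp_overlap"] = probes["snp_overlap"].astype(bool)
    variants = pd.read_csv(variants_path, sep="\t", dtype=str)
    go_raw = pd.read_csv(go_path, sep="\t", dtype=str).fillna("")
    go = pd.DataFrame({
        "term_id": go_raw["term_id"],
        "name": go_raw["name"],
        "parents": [p.split(",") if p else [] for p in go_raw["parents"]],
        "genes": [gset.split(",") if gset else [] for gset in go_raw["genes"]],
    })
    return AnnotationTables(genes, probes, variants, go)


def write_annotations(ann: AnnotationTables, genes_path, probes_path,
                      variants_path, go_path) -> None:
    ann.genes.to_csv(genes_path, sep="\t", index=False, float_format="%.10g")
    ann.probes.to_csv(probes_path, sep="\t", index=False)
    ann.variants.to_csv(variants_path, sep="\t", index=False)
    go = pd.DataFrame({
        "term_id": ann.go_terms["term_id"],
        "name": ann.go_terms["name"],
        "parents": [",".join(p) for p in ann.go_terms["parents"]],
        "genes": [",".join(gs) for gs in ann.go_terms["genes"]],
    })
    go.to_csv(go_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# genome scans
# ---------------------------------------------------------------------------

def write_scan(scan, path) -> None:
    """Write a QTLScan as TSV ordered by map position (chromosome, cM)."""
    df = scan.to_frame()
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_scan(path):
    from .mapping import QTLScan  # local import to avoid a cycle

    df = pd.read_csv(path, sep="\t", dtype={"chromosome": str})
    positions = df[["chromosome", "cM", "Mb"]].copy()
    return QTLScan(positions=positions,
                   lrs=df["LRS"].to_numpy(float),
                   additive=df["additive"].to_numpy(float),
                   method=str(df["method"].iloc[0]) if "method" in df else "HK")
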