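"""Domain containers, validation, and TSV readers/writers for region-level data.

A *region* is a window centred on one gene and holds three aligned blocks
measured on the same individuals: a genotype dosage matrix (n x s), a
chromatin-mark signal matrix (n x t, one column per peak of any assay type),
and an expression vector (n).  Summary form replaces the raw blocks with Wald
Z-scores and the SNP/mark correlation matrices that the fine-mapping model
consumes.

File dialect: tab-separated UTF-8 with mandatory row and column headers; the
first column of every matrix file carries individual ids (or row labels for
square correlation matrices).  Individuals are aligned across files by id,
never by row order.  Genomic coordinates, when present, follow the BED
convention (0-based, half-open) and are reporting metadata only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("chromapath")

_FLOAT_FMT = "%.12g"  # >=10 significant digits survive a write/read round trip


class ValidationError(ValueError):
    """Raised when region inputs violate a structural invariant."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class RegionDataset:
    """Individual-level genotype, chromatin and expression data for one region."""

    genotypes: np.ndarray  # n x s
    marks: np.ndarray  # n x t
    expression: np.ndarray  # n
    snp_ids: list[str]
    mark_ids: list[str]
    mark_types: list[str] | None = None
    gene_id: str = "gene"
    snp_positions: np.ndarray | None = None
    mark_intervals: np.ndarray | None = None  # t x 2, half-open
    tss: int | None = None

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.marks = np.asarray(self.marks, dtype=float)
        self.expression = np.asarray(self.expression, dtype=float).ravel()
        n = self.genotypes.shape[0]
        if self.marks.shape[0] != n or self.expression.shape[0] != n:
            raise ValidationError(
                f"sample-size mismatch: genotypes n={n}, marks n={self.marks.shape[0]}, "
                f"expression n={self.expression.shape[0]}"
            )
        if self.s < 1 or self.t < 1:
            raise ValidationError("need at least one SNP and one mark")
        for name, block in (
            ("genotypes", self.genotypes),
            ("marks", self.marks),
            ("expression", self.expression),
        ):
            if not np.all(np.isfinite(block)):
                raise ValidationError(f"{name} contains missing/non-finite values")
        if len(self.snp_ids) != self.s:
            raise ValidationError("snp_ids length does not match genotype columns")
        if len(self.mark_ids) != self.t:
            raise ValidationError("mark_ids length does not match mark columns")
        if self.mark_types is not None and len(self.mark_types) != self.t:
            raise ValidationError("mark_types length does not match mark columns")
        sd = self.genotypes.std(axis=0)
        if np.any(sd == 0):
            bad = [self.snp_ids[j] for j in np.flatnonzero(sd == 0)]
            raise ValidationError(f"constant genotype column(s): {bad}")

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def s(self) -> int:
        return self.genotypes.shape[1]

    @property
    def t(self) -> int:
        return self.marks.shape[1]


@dataclass
class RegionSummary:
    """Summary-statistic view of a region: Z-scores plus correlation matrices.

    ``Zg`` holds SNP-mark Wald Z-scores (s x t), ``Zh`` mark-expression scores
    (t), ``Zge`` SNP-expression scores (s; used by baselines and diagnostics),
    ``sigma_g``/``sigma_h`` the SNP (LD) and mark correlation matrices.
    """

    Zg: np.ndarray
    Zh: np.ndarray
    Zge: np.ndarray
    sigma_g: np.ndarray
    sigma_h: np.ndarray
    n: int
    snp_ids: list[str] | None = None
    mark_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.Zg = np.asarray(self.Zg, dtype=float)
        self.Zh = np.asarray(self.Zh, dtype=float).ravel()
        self.Zge = np.asarray(self.Zge, dtype=float).ravel()
        self.sigma_g = np.asarray(self.sigma_g, dtype=float)
        self.sigma_h = np.asarray(self.sigma_h, dtype=float)
        s, t = self.Zg.shape
        if self.Zh.shape[0] != t:
            raise ValidationError("Zh length inconsistent with Zg columns")
        if self.Zge.shape[0] != s:
            raise ValidationError("Zge length inconsistent with Zg rows")
        for name, mat, dim in (("sigma_g", self.sigma_g, s), ("sigma_h", self.sigma_h, t)):
            if mat.shape != (dim, dim):
                raise ValidationError(f"{name} must be {dim}x{dim}, got {mat.shape}")
            if not np.allclose(mat, mat.T, atol=1e-8):
                raise ValidationError(f"{name} is not symmetric")
            if not np.allclose(np.diag(mat), 1.0, atol=1e-6):
                raise ValidationError(f"{name} diagonal is not 1")
            if np.any(np.abs(mat) > 1 + 1e-8):
                raise ValidationError(f"{name} has |correlation| > 1")
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(s)]
        if self.mark_ids is None:
            self.mark_ids = [f"mark{k}" for k in range(t)]

    @property
    def s(self) -> int:
        return self.Zg.shape[0]

    @property
    def t(self) -> int:
        return self.Zg.shape[1]


@dataclass
class CausalConfig:
    """Ground truth for a simulated region.

    ``causal_paths`` lists the true (snp, mark) pairs; for reversed-order or
    independent-effect scenarios the pair is the (SNP, affected mark) couple
    even though no mediated path exists.
    """

    causal_snps: list[int]
    causal_marks: list[int]
    scenario: str = "standard"
    beta_g: list[float] = field(default_factory=list)
    beta_h: list[float] = field(default_factory=list)
    var_explained_g: float = 0.25
    var_explained_h: float = 0.25
    causal_paths: list[tuple[int, int]] = field(default_factory=list)

    _SCENARIOS = (
        "standard",
        "multi_snp",
        "multi_mark",
        "violation1",
        "violation2",
        "violation3",
        "violation4",
        "violation5",
        "violation6",
        "violation7",
    )

    def __post_init__(self) -> None:
        if self.scenario not in self._SCENARIOS:
            raise ValidationError(f"unknown scenario {self.scenario!r}")
        for frac in (self.var_explained_g, self.var_explained_h):
            if not (0 <= frac < 1):
                raise ValidationError("variance fractions must lie in [0, 1)")
        if not self.causal_paths:
            self.causal_paths = [
                (c, d) for c in self.causal_snps for d in self.causal_marks
            ]


@dataclass
class PathPosterior:
    """Posterior over all single-SNP/single-mark causal paths in a region."""

    path_probs: np.ndarray  # s x t
    snp_marginals: np.ndarray = None  # type: ignore[assignment]
    mark_marginals: np.ndarray = None  # type: ignore[assignment]
    log_evidence: float = np.nan
    snp_ids: list[str] | None = None
    mark_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.path_probs = np.asarray(self.path_probs, dtype=float)
        if self.snp_marginals is None:
            self.snp_marginals = self.path_probs.sum(axis=1)
        if self.mark_marginals is None:
            self.mark_marginals = self.path_probs.sum(axis=0)
        self.snp_marginals = np.asarray(self.snp_marginals, dtype=float)
        self.mark_marginals = np.asarray(self.mark_marginals, dtype=float)
        if np.any(self.path_probs < 0):
            raise ValidationError("negative path probability")
        if abs(self.path_probs.sum() - 1.0) > 1e-8:
            raise ValidationError("path probabilities do not sum to 1")
        if not np.allclose(self.snp_marginals, self.path_probs.sum(axis=1), atol=1e-8):
            raise ValidationError("snp_marginals inconsistent with path_probs row sums")
        if not np.allclose(self.mark_marginals, self.path_probs.sum(axis=0), atol=1e-8):
            raise ValidationError("mark_marginals inconsistent with path_probs column sums")
        s, t = self.path_probs.shape
        if self.snp_ids is None:
            self.snp_ids = [f"snp{j}" for j in range(s)]
        if self.mark_ids is None:
            self.mark_ids = [f"mark{k}" for k in range(t)]


@dataclass
class ModelPrior:
    """Model hyper-parameters.

    prior_ncp_var
        Prior variance of the causal mark's non-centrality parameter on the
        Z-score scale (default 5; performance is flat over roughly 5-10).
    diag_eps
        Ridge added along the diagonal of the causal-NCP prior covariance to
        keep it positive definite (default 1e-4).
    path_prior
        s x t matrix of per-path prior probabilities, or None for uniform
        1/(s*t).
    """

    prior_ncp_var: float = 5.0
    diag_eps: float = 1e-4
    path_prior: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.prior_ncp_var <= 0:
            raise ValidationError("prior_ncp_var must be > 0")
        if self.diag_eps <= 0:
            raise ValidationError("diag_eps must be > 0")
        if self.path_prior is not None:
            self.path_prior = np.asarray(self.path_prior, dtype=float)
            if np.any(self.path_prior < 0) or abs(self.path_prior.sum() - 1) > 1e-8:
                raise ValidationError("path_prior must be non-negative and sum to 1")

    def path_prior_for(self, s: int, t: int) -> np.ndarray:
        if self.path_prior is None:
            return np.full((s, t), 1.0 / (s * t))
        if self.path_prior.shape != (s, t):
            raise ValidationError(
                f"path_prior shape {self.path_prior.shape} does not match region ({s}, {t})"
            )
        return self.path_prior


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize(m: np.ndarray) -> np.ndarray:
    """Column-standardize to mean 0 and unit sample variance (ddof=1).

    Raises ValidationError naming the first constant column.
    """
    m = np.atleast_2d(np.asarray(m, dtype=float))
    squeeze = False
    if m.shape[0] == 1 and m.size > 1:  # row vector: treat as single column
        m = m.T
        squeeze = True
    sd = m.std(axis=0, ddof=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValidationError(f"column {bad} is constant and cannot be standardized")
    out = (m - m.mean(axis=0)) / sd
    return out.ravel() if squeeze else out


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def _read_matrix(path: Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise ValidationError(f"{path}: duplicate row ids")
    if df.columns.has_duplicates:
        raise ValidationError(f"{path}: duplicate column ids")
    if df.isna().any().any():
        col = df.columns[df.isna().any().to_numpy()][0]
        raise ValidationError(f"{path}: missing values in column {col!r}")
    return df


def read_region(
    genotypes: str | Path,
    marks: str | Path,
    expression: str | Path,
    descriptor: str | Path | None = None,
    mark_metadata: str | Path | None = None,
) -> RegionDataset:
    """Read one region from TSV files, aligning individuals by id.

    ``expression`` is an n x 1 TSV.  The optional JSON ``descriptor`` supplies
    gene_id/TSS; optional ``mark_metadata`` supplies mark types and intervals.
    """
    g = _read_matrix(Path(genotypes))
    h = _read_matrix(Path(marks))
    e = _read_matrix(Path(expression))
    ids = g.index
    for name, df in (("marks", h), ("expression", e)):
        if set(df.index) != set(ids):
            raise ValidationError(
                f"{name} file individuals do not match genotypes file"
            )
    h = h.loc[ids]
    e = e.loc[ids]
    if e.shape[1] != 1:
        raise ValidationError("expression file must have exactly one value column")

    gene_id, tss = "gene", None
    if descriptor is not None:
        meta = json.loads(Path(descriptor).read_text())
        gene_id = meta.get("gene_id", gene_id)
        tss = meta.get("tss")

    mark_types = None
    mark_intervals = None
    if mark_metadata is not None:
        mm = pd.read_csv(Path(mark_metadata), sep="\t").set_index("mark_id")
        mm = mm.loc[h.columns]
        mark_types = mm["mark_type"].tolist()
        if {"start", "end"} <= set(mm.columns):
            mark_intervals = mm[["start", "end"]].to_numpy(dtype=int)

    return RegionDataset(
        genotypes=g.to_numpy(),
        marks=h.to_numpy(),
        expression=e.to_numpy().ravel(),
        snp_ids=[str(c) for c in g.columns],
        mark_ids=[str(c) for c in h.columns],
        mark_types=mark_types,
        gene_id=gene_id,
        mark_intervals=mark_intervals,
        tss=tss,
    )


def write_region(d: RegionDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write a RegionDataset as the three-matrix TSV bundle plus descriptor."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ids = [f"ind{i}" for i in range(d.n)]
    paths = {}
    for name, frame in (
        ("genotypes", pd.DataFrame(d.genotypes, index=ids, columns=d.snp_ids)),
        ("marks", pd.DataFrame(d.marks, index=ids, columns=d.mark_ids)),
        ("expression", pd.DataFrame({d.gene_id: d.expression}, index=ids)),
    ):
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", float_format=_FLOAT_FMT, index_label="individual_id")
        paths[name] = p
    desc = {"gene_id": d.gene_id, "tss": d.tss}
    p = out / "region.json"
    p.write_text(json.dumps(desc, indent=1))
    paths["descriptor"] = p
    return paths


def write_summary(summ: RegionSummary, out_dir: str | Path) -> dict[str, Path]:
    """Write a RegionSummary as TSVs (Zg, Zh, Zge, sigma_g, sigma_h)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = {
        "Zg": pd.DataFrame(summ.Zg, index=summ.snp_ids, columns=summ.mark_ids),
        "Zh": pd.DataFrame({"z": summ.Zh}, index=summ.mark_ids),
        "Zge": pd.DataFrame({"z": summ.Zge}, index=summ.snp_ids),
        "sigma_g": pd.DataFrame(summ.sigma_g, index=summ.snp_ids, columns=summ.snp_ids),
        "sigma_h": pd.DataFrame(summ.sigma_h, index=summ.mark_ids, columns=summ.mark_ids),
    }
    paths = {}
    for name, frame in frames.items():
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", float_format=_FLOAT_FMT, index_label="id")
        paths[name] = p
    (out / "summary.json").write_text(json.dumps({"n": summ.n}))
    paths["meta"] = out / "summary.json"
    return paths


def read_summary(in_dir: str | Path) -> RegionSummary:
    """Read a RegionSummary written by :func:`write_summary`."""
    d = Path(in_dir)
    Zg = _read_matrix(d / "Zg.tsv")
    Zh = _read_matrix(d / "Zh.tsv")
    Zge = _read_matrix(d / "Zge.tsv")
    sg = _read_matrix(d / "sigma_g.tsv")
    sh = _read_matrix(d / "sigma_h.tsv")
    n = json.loads((d / "summary.json").read_text())["n"]
    return RegionSummary(
        Zg=Zg.to_numpy(),
        Zh=Zh.to_numpy().ravel(),
        Zge=Zge.to_numpy().ravel(),
        sigma_g=sg.to_numpy(),
        sigma_h=sh.to_numpy(),
        n=n,
        snp_ids=[str(i) for i in Zg.index],
        mark_ids=[str(c) for c in Zg.columns],
    )


def write_results(p: PathPosterior, out_dir: str | Path, header: str | None = None) -> dict[str, Path]:
    """Write posterior results: paths.tsv (descending) plus marginal tables.

    ``header`` lines (e.g. seed/config provenance) are prepended as comments.
    """
    out = Path(out_dir)
    if not out.exists():
        logger.info("creating output directory %s", out)
        out.mkdir(parents=True)
    s, t = p.path_probs.shape
    rows = pd.DataFrame(
        {
            "snp_id": np.repeat(p.snp_ids, t),
            "mark_id": np.tile(p.mark_ids, s),
            "posterior": p.path_probs.ravel(),
        }
    ).sort_values("posterior", ascending=False, kind="stable")
    tables = {
        "paths": rows,
        "snp_marginals": pd.DataFrame(
            {"snp_id": p.snp_ids, "posterior": p.snp_marginals}
        ).sort_values("posterior", ascending=False, kind="stable"),
        "mark_marginals": pd.DataFrame(
            {"mark_id": p.mark_ids, "posterior": p.mark_marginals}
        ).sort_values("posterior", ascending=False, kind="stable"),
    }
    paths = {}
    for name, frame in tables.items():
        fp = out / f"{name}.tsv"
        with open(fp, "w") as fh:
            if header:
                for line in header.splitlines():
                    fh.write(f"# {line}\n")
            frame.to_csv(fh, sep="\t", float_format=_FLOAT_FMT, index=False)
        paths[name] = fp
    return paths


def read_results(out_dir: str | Path) -> PathPosterior:
    """Reconstruct a PathPosterior from a results directory."""
    d = Path(out_dir)
    rows = pd.read_csv(d / "paths.tsv", sep="\t", comment="#")
    snp_ids = list(dict.fromkeys(rows["snp_id"].astype(str)))
    mark_ids = list(dict.fromkeys(rows["mark_id"].astype(str)))
    wide = rows.pivot(index="snp_id", columns="mark_id", values="posterior")
    wide = wide.loc[snp_ids, mark_ids]
    return PathPosterior(
        path_probs=wide.to_numpy(), snp_ids=snp_ids, mark_ids=mark_ids
    )
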