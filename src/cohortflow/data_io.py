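"""Expression-matrix I/O, gene filtering, duplicate resolution and TMM scaling.

The in-memory container is a genes x samples matrix of non-negative values.
Count data (``data_kind="counts"``) passes through CPM-based gene filtering
and trimmed-mean-of-M-values (TMM) between-sample normalization; pre-normalized
data (``data_kind="normalized"``, e.g. RMA microarray intensities) skips both
and only goes through duplicate-identifier resolution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

COUNTS = "counts"
NORMALIZED = "normalized"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with row/column identifiers.

    Parameters
    ----------
    values
        Non-negative real matrix, one row per gene, one column per sample.
    gene_ids, sample_ids
        Unique string identifiers aligned with the rows / columns.
    data_kind
        ``"counts"`` for raw RNA-seq counts, ``"normalized"`` for intensities
        that were already scaled upstream (microarray RMA, externally
        batch-corrected matrices, ...).
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    data_kind: str = COUNTS

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D genes x samples matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("gene_ids are not unique")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        if np.any(self.values < 0):
            raise ValueError("expression values must be non-negative")
        if self.data_kind not in (COUNTS, NORMALIZED):
            raise ValueError(f"unknown data_kind {self.data_kind!r}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def library_sizes(self) -> np.ndarray:
        """Per-sample column sums."""
        return self.values.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, data_kind: str = COUNTS) -> "ExpressionMatrix":
        return cls(
            values=df.to_numpy(dtype=float),
            gene_ids=[str(g) for g in df.index],
            sample_ids=[str(s) for s in df.columns],
            data_kind=data_kind,
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(
            self.values[:, cols], list(self.gene_ids), list(sample_ids), self.data_kind
        )


@dataclass
class SampleMeta:
    """Per-sample clinical metadata.

    ``visit_rank`` is the 0-based order of the visit within its patient;
    ``visit_label`` the study's name for it (e.g. ``"WK0"``, ``"D3"``).
    """

    sample_id: str
    patient_id: str
    visit_rank: int
    visit_label: str = ""
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.visit_rank < 0:
            raise ValueError("visit_rank must be non-negative")


def validate_meta(meta: Sequence[SampleMeta]) -> None:
    """Check the (patient_id, visit_rank) uniqueness invariant."""
    seen: set[tuple[str, int]] = set()
    sids: set[str] = set()
    for m in meta:
        key = (m.patient_id, m.visit_rank)
        if key in seen:
            raise ValueError(f"duplicate visit {key} in metadata")
        seen.add(key)
        if m.sample_id in sids:
            raise ValueError(f"duplicate sample_id {m.sample_id!r} in metadata")
        sids.add(m.sample_id)


# ---------------------------------------------------------------------------
# Gene filtering and duplicate resolution
# ---------------------------------------------------------------------------

def cpm(m: ExpressionMatrix) -> np.ndarray:
    """Counts per million, per gene and sample, using column library sizes."""
    lib = m.library_sizes()
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(
            f"sample {m.sample_ids[zero[0]]!r} has zero library size; CPM undefined"
        )
    return m.values / lib[None, :] * 1e6


def filter_genes_cpm(
    m: ExpressionMatrix, cpm_threshold: float = 0.25, min_fraction: float = 0.01
) -> ExpressionMatrix:
    """Keep genes whose CPM strictly exceeds ``cpm_threshold`` in at least
    ``ceil(min_fraction * n_samples)`` samples.

    The comparison is strict (``> threshold``); CPM denominators are the
    column sums of the *input* matrix, so the filter is idempotent with
    respect to the gene set (library sizes of the filtered matrix are not
    re-used).
    """
    if m.data_kind != COUNTS:
        raise ValueError("CPM filtering requires count data")
    if cpm_threshold <= 0:
        raise ValueError("cpm_threshold must be positive")
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    min_samples = math.ceil(min_fraction * m.n_samples)
    passing = (cpm(m) > cpm_threshold).sum(axis=1) >= min_samples
    kept = np.flatnonzero(passing)
    logger.info(
        "CPM filter kept %d/%d genes (>%g CPM in >=%d samples)",
        kept.size, m.n_genes, cpm_threshold, min_samples,
    )
    return ExpressionMatrix(
        m.values[kept], [m.gene_ids[i] for i in kept], list(m.sample_ids), m.data_kind
    )


def dedupe_genes(
    m: ExpressionMatrix, id_map: Mapping[str, str] | None = None
) -> ExpressionMatrix:
    """Collapse rows mapping to the same symbol, keeping the highest-mean row.

    ``id_map`` maps each gene_id to a symbol (identity when omitted). Row
    means are arithmetic means of the values as given; ties are broken by
    first occurrence in input order. Output gene_ids are the symbols.
    """
    if id_map is None:
        id_map = {g: g for g in m.gene_ids}
    missing = [g for g in m.gene_ids if g not in id_map]
    if missing:
        raise ValueError(f"id_map does not cover gene_ids, e.g. {missing[0]!r}")
    means = m.values.mean(axis=1)
    best: dict[str, int] = {}
    order: list[str] = []
    for i, g in enumerate(m.gene_ids):
        sym = str(id_map[g])
        if sym not in best:
            best[sym] = i
            order.append(sym)
        elif means[i] > means[best[sym]]:  # strict: ties keep first occurrence
            best[sym] = i
    rows = [best[sym] for sym in order]
    return ExpressionMatrix(m.values[rows], order, list(m.sample_ids), m.data_kind)


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair_factor(
    obs: np.ndarray,
    ref: np.ndarray,
    lib_obs: float,
    lib_ref: float,
    log_ratio_trim: float = 0.3,
    sum_trim: float = 0.05,
    weighted: bool = True,
) -> float:
    """TMM scaling factor of one sample against the reference sample.

    Doubly trims genes by their rank in M (log ratio) and A (log average
    abundance), then takes the precision-weighted mean of the surviving M
    values; the factor is 2 to that mean.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        p_obs = obs / lib_obs
        p_ref = ref / lib_ref
        m_vals = np.log2(p_obs / p_ref)
        a_vals = 0.5 * np.log2(p_obs * p_ref)
    finite = np.isfinite(m_vals) & np.isfinite(a_vals) & (a_vals > -1e10)
    m_vals, a_vals = m_vals[finite], a_vals[finite]
    obs_f, ref_f = obs[finite], ref[finite]
    if m_vals.size == 0 or np.max(np.abs(m_vals)) < 1e-6:
        return 1.0
    n = m_vals.size
    lo_m = np.floor(n * log_ratio_trim) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * sum_trim) + 1
    hi_a = n + 1 - lo_a
    # ranks are 1-based average ranks (matches edgeR's trimming convention)
    rank_m = pd.Series(m_vals).rank().to_numpy()
    rank_a = pd.Series(a_vals).rank().to_numpy()
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(keep):
        return 1.0
    if weighted:
        # binomial (delta-method) variance of M as inverse precision weight
        w = (lib_obs - obs_f) / (lib_obs * obs_f) + (lib_ref - ref_f) / (lib_ref * ref_f)
        f = np.sum(m_vals[keep] / w[keep]) / np.sum(1.0 / w[keep])
    else:
        f = np.mean(m_vals[keep])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(
    m: ExpressionMatrix,
    ref_sample: str | None = None,
    log_ratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> dict[str, float]:
    """Trimmed-mean-of-M-values scaling factor per sample.

    The reference sample, when not given, is the one whose 75th-percentile
    CPM is closest to the mean 75th percentile across samples. Factors are
    renormalized so their log-mean is zero; normalized expression downstream
    is CPM divided by the factor.
    """
    if m.data_kind != COUNTS:
        raise ValueError("TMM requires count data")
    if m.n_samples < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = m.library_sizes()
    zero = np.flatnonzero(lib == 0)
    if zero.size:
        raise ValueError(f"sample {m.sample_ids[zero[0]]!r} has zero library size")
    if ref_sample is None:
        uq = np.quantile(m.values / lib[None, :], 0.75, axis=0)
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = m.sample_ids.index(ref_sample)
    ref = m.values[:, ref_idx]
    factors = np.array(
        [
            _tmm_pair_factor(
                m.values[:, j], ref, lib[j], lib[ref_idx],
                log_ratio_trim=log_ratio_trim, sum_trim=sum_trim,
            )
            for j in range(m.n_samples)
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return dict(zip(m.sample_ids, factors))


def normalize_counts(m: ExpressionMatrix, factors: Mapping[str, float]) -> ExpressionMatrix:
    """CPM normalization with TMM-adjusted (effective) library sizes."""
    f = np.array([factors[s] for s in m.sample_ids])
    lib = m.library_sizes()
    vals = m.values / (lib * f)[None, :] * 1e6
    return ExpressionMatrix(vals, list(m.gene_ids), list(m.sample_ids), NORMALIZED)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

META_COLUMNS = ("sample_id", "patient_id", "visit_rank", "visit_label")


def read_meta(path: str | Path) -> list[SampleMeta]:
    """Read sample metadata from delimited text (columns: sample_id,
    patient_id, visit_rank, optional visit_label; remaining columns become
    covariates)."""
    df = pd.read_csv(path, sep=None, engine="python")
    for col in ("sample_id", "patient_id", "visit_rank"):
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicated sample_id {dup!r} in metadata")
    extra = [c for c in df.columns if c not in META_COLUMNS]
    meta = []
    for _, row in df.iterrows():
        meta.append(
            SampleMeta(
                sample_id=str(row["sample_id"]),
                patient_id=str(row["patient_id"]),
                visit_rank=int(row["visit_rank"]),
                visit_label=str(row["visit_label"]) if "visit_label" in df.columns else "",
                covariates={c: row[c] for c in extra},
            )
        )
    validate_meta(meta)
    return meta


def write_meta(meta: Sequence[SampleMeta], path: str | Path) -> None:
    rows = []
    for s in meta:
        row = {
            "sample_id": s.sample_id,
            "patient_id": s.patient_id,
            "visit_rank": s.visit_rank,
            "visit_label": s.visit_label,
        }
        row.update(s.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_expression(
    path: str | Path, fmt: str = "delimited", data_kind: str = COUNTS
) -> ExpressionMatrix:
    """Read a genes x samples matrix.

    ``fmt="delimited"``: text with genes in rows, header row of sample IDs.
    ``fmt="mtx"``: matrix-market triplet plus sidecar ``<stem>.rownames.txt``
    and ``<stem>.colnames.txt`` files (one identifier per line).
    ``fmt="h5ad"``: AnnData container; samples are observations there, so the
    matrix is transposed on load.
    """
    path = Path(path)
    if fmt == "delimited":
        df = pd.read_csv(path, sep=None, engine="python", index_col=0)
        return ExpressionMatrix.from_frame(df, data_kind)
    if fmt == "mtx":
        from scipy.io import mmread

        vals = np.asarray(mmread(path).todense(), dtype=float)
        stem = path.with_suffix("")
        genes = Path(f"{stem}.rownames.txt").read_text().split()
        samples = Path(f"{stem}.colnames.txt").read_text().split()
        return ExpressionMatrix(vals, genes, samples, data_kind)
    if fmt == "h5ad":
        import anndata as ad

        adata = ad.read_h5ad(path)
        x = adata.X
        if not isinstance(x, np.ndarray):
            x = x.toarray()
        return ExpressionMatrix(
            np.asarray(x, dtype=float).T,
            [str(v) for v in adata.var_names],
            [str(o) for o in adata.obs_names],
            data_kind,
        )
    raise ValueError(f"unknown format {fmt!r}")


def write_expression(m: ExpressionMatrix, path: str | Path, fmt: str = "delimited") -> None:
    path = Path(path)
    if fmt == "delimited":
        m.to_frame().to_csv(path, sep="\t")
    elif fmt == "mtx":
        from scipy.io import mmwrite
        from scipy.sparse import coo_matrix

        mmwrite(str(path), coo_matrix(m.values))
        stem = path.with_suffix("")
        Path(f"{stem}.rownames.txt").write_text("\n".join(m.gene_ids) + "\n")
        Path(f"{stem}.colnames.txt").write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")


def write_factors(factors: Mapping[str, float], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tfactor\n")
        for sid, f in factors.items():
            fh.write(f"{sid}\t{f:.10g}\n")


def load_dataset(
    expr_path: str | Path,
    meta_path: str | Path,
    fmt: str = "delimited",
    data_kind: str = COUNTS,
) -> tuple[ExpressionMatrix, list[SampleMeta]]:
    """Read expression + metadata and join them on sample_id.

    Samples present in only one of the two inputs are dropped with a logged
    warning; zero overlap is an error.
    """
    m = read_expression(expr_path, fmt=fmt, data_kind=data_kind)
    meta = read_meta(meta_path)
    in_meta = {s.sample_id for s in meta}
    common = [s for s in m.sample_ids if s in in_meta]
    if not common:
        raise ValueError("no overlapping samples between expression and metadata")
    n_drop = (len(m.sample_ids) - len(common)) + (len(meta) - len(common))
    if n_drop:
        logger.warning(
            "dropping %d samples present in only one input (%d shared)",
            n_drop, len(common),
        )
    common_set = set(common)
    m = m.subset_samples(common)
    meta = [s for s in meta if s.sample_id in common_set]
    return m, meta
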