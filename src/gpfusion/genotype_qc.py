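"""Genotype quality control and genomic relationship matrices.

Raw SNP-array calls (``AA``/``AB``/``BB``/missing) are filtered with the
standard breeding-panel rules — excess heterozygosity, missingness, minor
allele frequency — recoded to single-copy 0/1 dosages, mean-imputed, and
turned into a VanRaden-style genomic relationship matrix (GRM) ``G``.
An upper-triangular Cholesky factor ``L`` with ``G = LᵀL`` provides the
per-record genomic feature matrix ``Z_L Lᵀ`` consumed by the neural-network
and boosting models, so that the inner products of the feature rows
reconstruct the relationship structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CALLS = ("AA", "AB", "BB", "NA")


class QCError(ValueError):
    """Raised when quality control cannot produce a usable marker matrix."""


@dataclass
class GenotypeCalls:
    """Raw categorical genotype calls, lines x markers.

    ``calls`` holds strings in ``{"AA", "AB", "BB", "NA"}``; ``NA`` marks a
    missing call. Numeric 0/1 input is accepted by :func:`apply_qc` via
    :meth:`from_coded`.
    """

    line_ids: list[str]
    marker_ids: list[str]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=object)
        if self.calls.shape != (len(self.line_ids), len(self.marker_ids)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.line_ids)} lines x {len(self.marker_ids)} markers"
            )
        if len(self.line_ids) < 2 or len(self.marker_ids) < 1:
            raise ValueError("need at least 2 lines and 1 marker")
        bad = set(np.unique(self.calls.astype(str))) - set(VALID_CALLS)
        if bad:
            raise ValueError(f"invalid genotype calls: {sorted(bad)}")

    @classmethod
    def from_coded(cls, line_ids, marker_ids, x: np.ndarray) -> "GenotypeCalls":
        """Build from a numeric 0/1 matrix with NaN for missing."""
        x = np.asarray(x, dtype=float)
        calls = np.empty(x.shape, dtype=object)
        calls[x == 0] = "AA"
        calls[x == 1] = "BB"
        calls[np.isnan(x)] = "NA"
        if (calls == None).any():  # noqa: E711 - unfilled cells
            raise ValueError("coded genotypes must be 0, 1 or NaN")
        return cls(list(line_ids), list(marker_ids), calls)


@dataclass
class CodedGenotypes:
    """Post-QC single-copy dosage matrix.

    ``X`` is lines x markers with entries in [0, 1]; imputed cells carry the
    marker's mean dosage. ``maf`` is the per-marker minor allele frequency
    computed before imputation.
    """

    line_ids: list[str]
    marker_ids: list[str]
    X: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.maf = np.asarray(self.maf, dtype=float)


@dataclass
class GenomicFeatures:
    """GRM plus its Cholesky-derived feature transform.

    ``G = LᵀL - jitter·I`` with ``L`` upper triangular; ``jitter`` is the
    diagonal inflation that was needed to make ``G`` factorizable (0 for a
    positive-definite GRM). ``line_ids`` indexes the rows of ``G``.
    """

    line_ids: list[str]
    G: np.ndarray
    L: np.ndarray | None = None
    jitter: float = 0.0
    ZLstar: np.ndarray | None = None
    n_markers_used: int | None = None
    qc_log: dict = field(default_factory=dict)


def _call_stats(col: np.ndarray) -> tuple[int, int, int, int]:
    """Counts of (AA, AB, BB, NA) in one marker column."""
    aa = int(np.sum(col == "AA"))
    ab = int(np.sum(col == "AB"))
    bb = int(np.sum(col == "BB"))
    na = int(np.sum(col == "NA"))
    return aa, ab, bb, na


def apply_qc(
    calls: GenotypeCalls,
    het_max: float = 0.10,
    miss_max: float = 0.20,
    maf_min: float = 0.05,
) -> CodedGenotypes:
    """Filter, recode and impute a raw call matrix.

    The rules are applied in a fixed order:

    1. markers whose heterozygote (``AB``) fraction among non-missing calls
       exceeds ``het_max`` are removed;
    2. surviving ``AB`` calls are recoded to the more frequent homozygote;
    3. markers with missing fraction above ``miss_max`` are removed;
    4. calls are coded as the dosage of the B allele (``AA`` = 0, ``BB`` = 1)
       and markers with minor allele frequency below ``maf_min`` (computed on
       the non-missing coded values) are removed;
    5. residual missing cells are mean-imputed per marker.

    Returns a :class:`CodedGenotypes`; raises :class:`QCError` if no marker
    survives.
    """
    for name, v in (("het_max", het_max), ("miss_max", miss_max), ("maf_min", maf_min)):
        if not (0 <= v <= 1):
            raise ValueError(f"{name} must lie in [0, 1], got {v}")

    raw = calls.calls.astype(str)
    n_lines, n_markers = raw.shape
    keep_het, keep_miss, keep_maf = [], [], []
    coded_cols, mafs, kept_ids = [], [], []

    for k in range(n_markers):
        col = raw[:, k].copy()
        aa, ab, bb, na = _call_stats(col)
        n_obs = aa + ab + bb
        # all-missing markers fall to the missingness rule below
        if n_obs > 0 and ab / n_obs > het_max:
            continue
        keep_het.append(k)
        if ab > 0:
            # recode heterozygotes to the majority homozygote (ties -> AA)
            col[col == "AB"] = "AA" if aa >= bb else "BB"
            aa, ab, bb, na = _call_stats(col)
        if na / n_lines > miss_max:
            continue
        keep_miss.append(k)
        x = np.full(n_lines, np.nan)
        x[col == "AA"] = 0.0
        x[col == "BB"] = 1.0
        p = np.nanmean(x)
        maf = min(p, 1.0 - p)
        if maf < maf_min:
            continue
        keep_maf.append(k)
        x[np.isnan(x)] = p
        coded_cols.append(x)
        mafs.append(maf)
        kept_ids.append(calls.marker_ids[k])

    logger.info(
        "QC: %d markers in; %d pass het<=%.2f; %d pass miss<=%.2f; %d pass MAF>=%.3f",
        n_markers, len(keep_het), het_max, len(keep_miss), maf_min, len(keep_maf),
    )
    if not coded_cols:
        raise QCError("empty after QC: no marker passed all filters")
    return CodedGenotypes(
        line_ids=list(calls.line_ids),
        marker_ids=kept_ids,
        X=np.column_stack(coded_cols),
        maf=np.array(mafs),
    )


def vanraden_grm(coded: CodedGenotypes) -> GenomicFeatures:
    """Centered cross-product genomic relationship matrix.

    With per-marker mean dosage ``p_k`` and centered matrix
    ``M = X - 1pᵀ``, the GRM is ``G = MMᵀ / Σ_k p_k(1-p_k)`` — the
    single-copy analogue of VanRaden's method 1 for 0/1-coded genotypes.
    Monomorphic columns carry no information and are excluded from both the
    numerator and the scaling sum.
    """
    X = np.asarray(coded.X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("GRM requires at least 2 lines")
    if np.isnan(X).any():
        raise ValueError("GRM input must be imputed (no missing values)")
    p = X.mean(axis=0)
    poly = (p > 0) & (p < 1)
    denom = float(np.sum(p[poly] * (1.0 - p[poly])))
    if denom == 0.0:
        raise QCError("zero denominator: all markers are monomorphic")
    M = X[:, poly] - p[poly]
    G = (M @ M.T) / denom
    G = 0.5 * (G + G.T)  # symmetrize against round-off
    return GenomicFeatures(
        line_ids=list(coded.line_ids), G=G, n_markers_used=int(poly.sum())
    )


def cholesky_factor(
    G: np.ndarray, base_jitter: float = 1e-8, max_tries: int = 7
) -> GenomicFeatures:
    """Upper-triangular factor L with ``LᵀL = G + jitter·I``.

    A GRM from fewer markers than lines (or with duplicated lines) is
    singular, so the diagonal is inflated by ``base_jitter · 10^m`` for
    m = 0, 1, ... until the factorization succeeds; the jitter actually used
    is recorded on the result.
    """
    G = np.asarray(G, dtype=float)
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    jitters = [0.0] + [base_jitter * 10.0**m for m in range(max_tries)]
    for jit in jitters:
        try:
            C = np.linalg.cholesky(G + jit * np.eye(G.shape[0]))
        except np.linalg.LinAlgError:
            continue
        if jit > 0:
            logger.info("cholesky_factor: applied diagonal jitter %.3e", jit)
        # numpy returns lower C with C Cᵀ = G + jit I; L = Cᵀ is the
        # upper-triangular factor with LᵀL = G + jit I.
        return GenomicFeatures(
            line_ids=[str(i) for i in range(G.shape[0])], G=G, L=C.T, jitter=jit
        )
    lam_min = float(np.linalg.eigvalsh(G).min())
    raise np.linalg.LinAlgError(
        f"G not factorizable even with jitter {jitters[-1]:.1e}; "
        f"smallest eigenvalue {lam_min:.3e}"
    )


def genomic_inputs(features: GenomicFeatures, record_line_index: np.ndarray) -> np.ndarray:
    """Per-record genomic feature rows ``Z_L Lᵀ``.

    ``record_line_index[r]`` is the integer position in ``features.G`` of the
    line observed in record ``r``; row ``r`` of the output is that line's row
    of ``Lᵀ``. Row-wise inner products of the output reconstruct
    ``G + jitter·I``.
    """
    if features.L is None:
        raise ValueError("features has no Cholesky factor; call cholesky_factor first")
    idx = np.asarray(record_line_index, dtype=int)
    n = features.G.shape[0]
    bad = idx[(idx < 0) | (idx >= n)]
    if bad.size:
        raise KeyError(f"unknown line indices: {sorted(set(bad.tolist()))}")
    return features.L.T[idx, :]


def build_genomic_features(
    coded: CodedGenotypes, base_jitter: float = 1e-8
) -> GenomicFeatures:
    """Convenience: GRM + Cholesky factor in one call."""
    feats = vanraden_grm(coded)
    fac = cholesky_factor(feats.G, base_jitter=base_jitter)
    feats.L, feats.jitter = fac.L, fac.jitter
    return feats


# ---------------------------------------------------------------------------
# I/O: delimited-text genotype matrices and GRMs
# ---------------------------------------------------------------------------

def read_genotype_calls(path, sep: str = ",") -> GenotypeCalls:
    """Read a calls matrix: first column line id, header of marker ids,
    cells in {AA, AB, BB, NA} or {0, 1, NA}."""
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    vals = df.to_numpy(dtype=object)
    vals[(vals == "") | (vals == "NA") | (vals == "nan")] = "NA"
    uniq = set(np.unique(vals.astype(str)))
    if uniq <= {"0", "1", "NA", "0.0", "1.0"}:
        num = np.where(vals == "NA", "nan", vals).astype(float)
        return GenotypeCalls.from_coded(df.index.tolist(), df.columns.tolist(), num)
    return GenotypeCalls(df.index.tolist(), df.columns.tolist(), vals)


def write_coded_genotypes(coded: CodedGenotypes, path, sep: str = ",") -> None:
    pd.DataFrame(coded.X, index=coded.line_ids, columns=coded.marker_ids).to_csv(
        path, sep=sep
    )


def write_grm(features: GenomicFeatures, path, sep: str = ",") -> None:
    pd.DataFrame(features.G, index=features.line_ids, columns=features.line_ids).to_csv(
        path, sep=sep
    )


def read_grm(path, sep: str = ",") -> GenomicFeatures:
    df = pd.read_csv(path, sep=sep, index_col=0)
    return GenomicFeatures(line_ids=[str(c) for c in df.columns], G=df.to_numpy(float))
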