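"""VanRaden genomic relationship matrix and GRM-based PCA.

K = W W' / sum_j 2 p_j (1 - p_j), where W centers each genotype column by
twice its allele frequency (w_ij = m_ij - 2 p_j). Missing calls are
mean-imputed per SNP before centering, so they contribute zero to W.
"""

from __future__ import annotations

import numpy as np

from .types import DosageMatrix, GenotypeMatrix, GRM

__all__ = ["vanraden_grm", "grm_pca", "write_grm", "read_grm"]


def vanraden_grm(
    g: GenotypeMatrix | DosageMatrix, freq_convention: str = "alt"
) -> GRM:
    """Build the VanRaden GRM from hard calls or dosages.

    freq_convention
        ``"alt"`` (default): center by the alternate-allele frequency — the
        standard VanRaden construction. ``"maf"``: center by the minor-allele
        frequency (folded), provided because some pipelines describe p_j as
        the MAF; with this convention columns whose alt frequency exceeds 0.5
        are centered by the folded value instead.

    Monomorphic SNPs are excluded (they carry no relationship information and
    contribute zero to the denominator).
    """
    if freq_convention not in ("alt", "maf"):
        raise ValueError("freq_convention must be 'alt' or 'maf'")
    mat = g.numeric()  # (n, m), nan missing
    p = np.nanmean(mat, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("all SNPs are monomorphic; GRM denominator would be zero")
    mat = mat[:, poly]
    p = p[poly]
    if freq_convention == "maf":
        p = np.minimum(p, 1.0 - p)

    w = mat - 2.0 * p
    w[np.isnan(w)] = 0.0  # mean-imputed cells are exactly at the center
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    K = (w @ w.T) / denom
    K = (K + K.T) / 2.0
    return GRM(
        K=K,
        sample_ids=list(g.sample_ids),
        denominator=denom,
        n_snps_used=int(poly.sum()),
        freq_convention=freq_convention,
    )


def grm_pca(grm: GRM, n_components: int = 5) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Eigen-decomposition PCA of a GRM.

    Returns ``(eigenvalues, scores, variance_fractions)`` with eigenvalues in
    descending order, scores = eigenvector * sqrt(eigenvalue) (n x c), and
    per-component fractions of the total (positive-part) variance.
    """
    n = grm.n_samples
    if n_components > n:
        raise ValueError(f"n_components={n_components} exceeds n={n}")
    vals, vecs = np.linalg.eigh(grm.K)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    top_vals = vals[:n_components]
    scores = vecs[:, :n_components] * np.sqrt(np.clip(top_vals, 0.0, None))
    total = np.clip(vals, 0.0, None).sum()
    fractions = np.clip(top_vals, 0.0, None) / total if total > 0 else np.zeros_like(top_vals)
    return top_vals, scores, fractions


def write_grm(grm: GRM, prefix: str) -> None:
    """Write a GRM as TSV triplets (i, j, value) plus a sample-id file."""
    import pandas as pd

    iu = np.tril_indices(grm.n_samples)
    pd.DataFrame(
        {"i": iu[0] + 1, "j": iu[1] + 1, "k": grm.K[iu]}
    ).to_csv(f"{prefix}.grm.tsv", sep="\t", index=False)
    with open(f"{prefix}.grm.id", "w") as fh:
        for s in grm.sample_ids:
            fh.write(f"{s}\n")
    with open(f"{prefix}.grm.meta", "w") as fh:
        fh.write(f"denominator\t{grm.denominator!r}\n")
        fh.write(f"n_snps_used\t{grm.n_snps_used}\n")
        fh.write(f"freq_convention\t{grm.freq_convention}\n")


def read_grm(prefix: str) -> GRM:
    import pandas as pd

    trip = pd.read_csv(f"{prefix}.grm.tsv", sep="\t")
    with open(f"{prefix}.grm.id") as fh:
        ids = [line.strip() for line in fh if line.strip()]
    meta = {}
    with open(f"{prefix}.grm.meta") as fh:
        for line in fh:
            k, v = line.rstrip("\n").split("\t")
            meta[k] = v
    n = len(ids)
    K = np.zeros((n, n))
    K[trip["i"] - 1, trip["j"] - 1] = trip["k"]
    K = K + np.tril(K, -1).T
    return GRM(
        K=K,
        sample_ids=ids,
        denominator=float(meta["denominator"]),
        n_snps_used=int(meta["n_snps_used"]),
        freq_convention=meta.get("freq_convention", "alt"),
    )
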