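"""VCF / TSV ingestion, allele frequencies, the HWE exact test and variant QC.

Reading goes through :mod:`cyvcf2`; only biallelic SNPs are kept (indels and
multiallelic records are dropped and counted). Writing emits plain-text VCF so
that simulated truth/dosage sets round-trip through the same reader.
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .types import MISSING, DosageMatrix, GenotypeMatrix, PhenotypeTable, VariantMeta

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "allele_frequency",
    "minor_allele_frequency",
    "hwe_exact_test",
    "qc_filter",
    "QCResult",
]


# ---------------------------------------------------------------------------
# VCF reading / writing


def _is_biallelic_snp(ref: str, alts: list[str]) -> bool:
    return len(alts) == 1 and len(ref) == 1 and len(alts[0]) == 1 and ref != alts[0]


def read_genotypes(
    path: str | Path,
    field: str = "GT",
    info_tag: str = "INFO_SCORE",
    info_tag_fallback: str = "INFO",
) -> GenotypeMatrix | DosageMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` (GT) or :class:`DosageMatrix`.

    Parameters
    ----------
    path:
        VCF file, plain or bgzipped.
    field:
        ``"GT"`` for hard calls, ``"DS"`` for dosages, ``"GP"`` for genotype
        probability triples (dosage derived as P(het) + 2 P(hom-alt)).
    info_tag, info_tag_fallback:
        INFO keys probed (in order) for the per-variant imputation info score.

    Multiallelic and non-SNP records are dropped; the count is attached to the
    result as ``n_dropped_non_biallelic``. Records lacking the requested
    FORMAT field are skipped with a warning.
    """
    from cyvcf2 import VCF

    if field not in ("GT", "DS", "GP"):
        raise ValueError(f"field must be GT, DS or GP, got {field!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    n = len(samples)

    variants: list[VariantMeta] = []
    columns: list[np.ndarray] = []
    prob_columns: list[np.ndarray] = []
    n_dropped = 0
    n_skipped = 0

    for rec in vcf:
        if not _is_biallelic_snp(rec.REF, rec.ALT):
            n_dropped += 1
            continue
        score = rec.INFO.get(info_tag)
        if score is None:
            score = rec.INFO.get(info_tag_fallback)
        try:
            score = None if score is None else float(score)
        except (TypeError, ValueError):
            score = None
        meta = VariantMeta(str(rec.CHROM), int(rec.POS), rec.REF, rec.ALT[0], score)

        if field == "GT":
            g = rec.gt_types.astype(np.int8)  # 0/1/2, 3 = unknown (gts012)
            g[g == 3] = MISSING
            columns.append(g)
        elif field == "DS":
            ds = rec.format("DS")
            if ds is None:
                n_skipped += 1
                continue
            col = np.asarray(ds, dtype=float).reshape(n)
            col[(col < 0) | (col > 2)] = np.nan
            columns.append(col)
        else:  # GP
            gp = rec.format("GP")
            if gp is None:
                n_skipped += 1
                continue
            gp = np.asarray(gp, dtype=float).reshape(n, 3)
            columns.append(gp[:, 1] + 2.0 * gp[:, 2])
            prob_columns.append(gp)
        variants.append(meta)

    vcf.close()
    if n_skipped:
        warnings.warn(f"{n_skipped} records lacked FORMAT/{field} and were skipped")
    if not variants:
        raise ValueError(f"no biallelic SNPs with FORMAT/{field} found in {path}")

    if field == "GT":
        out: GenotypeMatrix | DosageMatrix = GenotypeMatrix(
            samples, variants, np.column_stack(columns)
        )
    else:
        probs = np.stack(prob_columns, axis=1) if prob_columns else None
        out = DosageMatrix(samples, variants, np.column_stack(columns), probs)
    out.n_dropped_non_biallelic = n_dropped  # type: ignore[attr-defined]
    return out


def write_genotypes(data: GenotypeMatrix | DosageMatrix, path: str | Path) -> None:
    """Write hard calls (GT) or dosages (DS, plus GP when present) as VCF."""
    path = Path(path)
    is_geno = isinstance(data, GenotypeMatrix)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        chroms = dict.fromkeys(v.chrom for v in data.variants)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##INFO=<ID=INFO_SCORE,Number=1,Type=Float,Description="Imputation info score">\n')
        if is_geno:
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fmt = "GT"
        else:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt-allele dosage">\n')
            fmt = "DS"
            if data.probs is not None:
                fh.write('##FORMAT=<ID=GP,Number=3,Type=Float,Description="Genotype probabilities">\n')
                fmt = "DS:GP"
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(data.sample_ids) + "\n")

        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j, v in enumerate(data.variants):
            info = "." if v.info_score is None else f"INFO_SCORE={v.info_score:.6g}"
            row = [v.chrom, str(v.pos), ".", v.ref, v.alt, ".", "PASS", info, fmt]
            if is_geno:
                row += [gt_strings[int(c)] for c in data.calls[:, j]]
            else:
                for i in range(data.n_samples):
                    d = data.dosages[i, j]
                    cell = "." if np.isnan(d) else f"{d:.6g}"
                    if data.probs is not None:
                        p = data.probs[i, j]
                        cell += ":" + ",".join(f"{x:.6g}" for x in p)
                    row.append(cell)
            fh.write("\t".join(row) + "\n")


def read_phenotypes(
    path: str | Path,
    trait_columns: list[str],
    id_column: str = "id",
    sex_column: str = "sex",
    house_column: str = "house",
) -> PhenotypeTable:
    """Read a phenotype/covariate TSV into a :class:`PhenotypeTable`."""
    df = pd.read_csv(path, sep="\t")
    for col in [id_column, sex_column, house_column, *trait_columns]:
        if col not in df.columns:
            raise ValueError(f"column {col!r} missing from {path}")
    return PhenotypeTable(
        sample_ids=[str(s) for s in df[id_column]],
        trait_names=list(trait_columns),
        trait_values=df[trait_columns].to_numpy(dtype=float),
        sex=df[sex_column].fillna(-1).to_numpy(dtype=int),
        house=df[house_column].fillna(-1).to_numpy(dtype=int),
    )


def write_phenotypes(ph: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"id": ph.sample_ids, "sex": ph.sex, "house": ph.house})
    for k, name in enumerate(ph.trait_names):
        df[name] = ph.trait_values[:, k]
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Allele frequencies


def allele_frequency(g: GenotypeMatrix | DosageMatrix, variant_index: int) -> float:
    """Alternate-allele frequency at one variant, over non-missing calls."""
    col = g.numeric()[:, variant_index]
    obs = ~np.isnan(col)
    if not obs.any():
        raise ValueError(f"all calls missing at variant {variant_index}")
    return float(col[obs].mean() / 2.0)


def minor_allele_frequency(g: GenotypeMatrix | DosageMatrix, variant_index: int) -> float:
    """MAF = min(p, 1-p) for the alternate-allele frequency p."""
    p = allele_frequency(g, variant_index)
    return min(p, 1.0 - p)


def _alt_freqs(mat: np.ndarray) -> np.ndarray:
    """Column-wise alt frequencies of a float matrix with nan missing."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return np.nanmean(mat, axis=0) / 2.0


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact HWE test p-value (Wigginton-style, no mid-p correction).

    Enumerates every heterozygote count compatible with the observed allele
    counts; the p-value is the total probability of outcomes no more likely
    than the observed one under Hardy-Weinberg proportions.
    """
    if min(n_homref, n_het, n_homalt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_rare = 2 * min(n_homref, n_homalt) + n_het  # rare-allele count
    # possible het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    rare_homs = (n_rare - hets) // 2
    common_homs = n - hets - rare_homs
    # P(het = h | allele counts) via log-factorials
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(rare_homs + 1)
        - gammaln(common_homs + 1)
        + hets * math.log(2.0)
        - gammaln(2 * n + 1)
        + gammaln(n_rare + 1)
        + gammaln(2 * n - n_rare + 1)
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    p_obs = probs[hets == n_het][0]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# QC filter


@dataclasses.dataclass
class QCResult:
    """Filtered data plus per-rule removal counts (first failing rule wins)."""

    data: GenotypeMatrix | DosageMatrix
    kept_indices: np.ndarray
    n_removed_maf: int
    n_removed_missing: int
    n_removed_hwe: int
    n_removed_info: int

    @property
    def removal_counts(self) -> tuple[int, int, int, int]:
        return (
            self.n_removed_maf,
            self.n_removed_missing,
            self.n_removed_hwe,
            self.n_removed_info,
        )

    def report(self) -> pd.DataFrame:
        """Per-variant QC report: chrom, pos, ref, alt, rule_failed."""
        raise_attr = getattr(self, "_rules", None)
        if raise_attr is None:
            raise RuntimeError("report not available")
        return self._rules  # type: ignore[return-value]


def qc_filter(
    g: GenotypeMatrix | DosageMatrix,
    maf_min: float = 0.05,
    miss_max: float = 0.1,
    hwe_min: float = 1e-6,
    info_min: float = 0.4,
) -> QCResult:
    """Variant QC: MAF, missingness, HWE and imputation-info-score filters.

    A variant survives iff MAF > ``maf_min``, missing rate < ``miss_max``,
    HWE exact p > ``hwe_min`` and (no info score OR info score > ``info_min``),
    all comparisons strict. Removal counts attribute each dropped variant to
    its first failing rule, in the order MAF, missingness, HWE, info.

    The HWE test needs hard genotype counts; for a :class:`DosageMatrix` the
    hard-called genotypes are used for both HWE and missingness.
    """
    mat = g.numeric()
    n, m = mat.shape
    if isinstance(g, DosageMatrix):
        hard = g.hard_calls().calls
    else:
        hard = g.calls

    obs = hard != MISSING
    n_obs = obs.sum(axis=0)
    miss_rate = 1.0 - n_obs / n
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p_alt = _alt_freqs(mat)
    maf = np.minimum(p_alt, 1.0 - p_alt)

    counts = [0, 0, 0, 0]
    keep = np.ones(m, dtype=bool)
    rules: list[str] = []
    for j in range(m):
        if not (n_obs[j] > 0 and maf[j] > maf_min):
            keep[j] = False
            counts[0] += 1
            rules.append("maf")
            continue
        if not (miss_rate[j] < miss_max):
            keep[j] = False
            counts[1] += 1
            rules.append("missing")
            continue
        col = hard[:, j]
        hwe_p = hwe_exact_test(
            int((col == 0).sum()), int((col == 1).sum()), int((col == 2).sum())
        )
        if not (hwe_p > hwe_min):
            keep[j] = False
            counts[2] += 1
            rules.append("hwe")
            continue
        score = g.variants[j].info_score
        if score is not None and not (score > info_min):
            keep[j] = False
            counts[3] += 1
            rules.append("info")
            continue
        rules.append("pass")

    kept = np.flatnonzero(keep)
    if kept.size == 0:
        warnings.warn("QC removed all variants")
        filtered = dataclasses.replace(
            g,
            variants=[],
            **(
                {"calls": g.calls[:, :0]}
                if isinstance(g, GenotypeMatrix)
                else {
                    "dosages": g.dosages[:, :0],
                    "probs": None if g.probs is None else g.probs[:, :0, :],
                }
            ),
        )
    else:
        filtered = g.take_variants(kept)

    res = QCResult(filtered, kept, *counts)
    res._rules = pd.DataFrame(  # type: ignore[attr-defined]
        {
            "chrom": [v.chrom for v in g.variants],
            "pos": [v.pos for v in g.variants],
            "ref": [v.ref for v in g.variants],
            "alt": [v.alt for v in g.variants],
            "rule_failed": rules,
        }
    )
    return res
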