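"""Variant QC, pathogenicity filtering, genotype association, and seed-gene selection.

Input is an ANNOVAR-style annotated variant table (one row per variant) with
per-sample genotype columns coded 0/1/2 (alternate-allele dose) or missing,
plus a sample sheet assigning each sample to the case or control group.

The stages implemented here:

1. low-quality flags on alignment/quality metrics — flagged variants are
   excluded from everything downstream;
2. pathogenicity/frequency filters (PolyPhen-2 HDIV >= 0.957, SIFT < 0.05,
   CADD > 10, population MAF < 0.05, coverage >= 10x);
3. case/control genotype association: Cochran–Armitage trend test, optionally
   with population-stratification adjustment by regressing out top principal
   components of the normalised genotype matrix (EIGENSTRAT-style);
4. per-sample seed genes: the top K genes a sample carries, ranked by the
   best association p-value among the sample's qualifying variants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Annotation columns, named as in ANNOVAR output.
ANNOTATION_COLUMNS = ("Polyphen2_HDIV_score", "SIFT_score", "CADD_phred", "ExAC_ALL")
#: Per-variant QC metric columns (GATK conventions: depth, Phred quality,
#: quality-by-depth, Phred-scaled strand-bias Fisher p).
QC_COLUMNS = ("DP", "QUAL", "QD", "FS")
CORE_COLUMNS = ("Chr", "Pos", "Gene")

GENOTYPE_MISSING = {".", "", "NA", "NaN", "nan", "./.", None}


# ---------------------------------------------------------------------------
# I/O

def read_variant_table(path) -> pd.DataFrame:
    """Read a TSV variant table; annotation/QC columns coerced to numeric (missing -> NaN)."""
    df = pd.read_csv(path, sep="\t", dtype={"Chr": str})
    for col in (*ANNOTATION_COLUMNS, *QC_COLUMNS, "AltMappings", "Pos"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def read_sample_sheet(path) -> pd.DataFrame:
    """Read a sample sheet TSV with at least ``sample_id`` and ``group`` columns."""
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "group"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing column(s): {sorted(missing)}")
    bad = set(sheet["group"]) - {"case", "control"}
    if bad:
        raise ValueError(f"sample sheet group values must be case/control, got {sorted(bad)}")
    return sheet


# ---------------------------------------------------------------------------
# Low-quality flags

#: rule name -> human-readable description
LOW_QUALITY_RULES = {
    "density>=3in10bp": "three or more variants within 10 bp on the same chromosome",
    "alt_mappings>=4": "four or more equally good alignment locations",
    "coverage<10": "coverage below ten reads",
    "qual<30": "quality score below 30",
    "qd<1.5": "variant confidence / unfiltered depth below 1.5",
    "fs>200": "Phred-scaled strand-bias Fisher p above 200",
}


def flag_low_quality(
    variant: pd.Series,
    neighborhood_positions: Sequence[int] = (),
) -> tuple[bool, list[str]]:
    """Apply the six low-quality rules to one variant.

    ``neighborhood_positions`` are the 1-based positions of OTHER variants on
    the same chromosome; the density rule fires when, counting the variant
    itself, three or more fall within the inclusive window ``pos +/- 10``.
    Missing metrics never fire a rule.
    """
    rules: list[str] = []
    pos = variant.get("Pos")
    if pos is not None and not pd.isna(pos):
        in_window = sum(1 for q in neighborhood_positions if abs(int(q) - int(pos)) <= 10)
        if in_window + 1 >= 3:
            rules.append("density>=3in10bp")

    def _num(key):
        v = variant.get(key)
        return None if v is None or pd.isna(v) else float(v)

    am = _num("AltMappings")
    if am is not None and am >= 4:
        rules.append("alt_mappings>=4")
    dp = _num("DP")
    if dp is not None and dp < 10:
        rules.append("coverage<10")
    qual = _num("QUAL")
    if qual is not None and qual < 30:
        rules.append("qual<30")
    qd = _num("QD")
    if qd is not None and qd < 1.5:
        rules.append("qd<1.5")
    fs = _num("FS")
    if fs is not None and fs > 200:
        rules.append("fs>200")
    return bool(rules), rules


def low_quality_flags(df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised low-quality screen for a whole table.

    Returns a DataFrame (same index) with boolean ``low_quality`` and a
    semicolon-joined ``rules`` column naming every rule that fired.
    """
    n = len(df)
    fired: list[list[str]] = [[] for _ in range(n)]

    # density: >= 3 variants within an inclusive +/-10 bp window per chromosome
    if {"Chr", "Pos"} <= set(df.columns):
        pos = pd.to_numeric(df["Pos"], errors="coerce")
        for _, idx in df.groupby("Chr", sort=False).groups.items():
            labels = np.asarray(idx)
            p = pos.loc[idx].to_numpy(dtype=float)
            valid = ~np.isnan(p)
            labels, p = labels[valid], p[valid]
            order = np.argsort(p, kind="stable")
            sorted_p = p[order]
            # window counts (inclusive +/-10 bp, including the variant itself)
            left = np.searchsorted(sorted_p, sorted_p - 10, side="left")
            right = np.searchsorted(sorted_p, sorted_p + 10, side="right")
            counts = right - left
            for k, row_label in enumerate(labels[order]):
                if counts[k] >= 3:
                    fired[df.index.get_loc(row_label)].append("density>=3in10bp")

    def _col(name):
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
        return np.full(n, np.nan)

    checks = [
        ("alt_mappings>=4", _col("AltMappings") >= 4),
        ("coverage<10", _col("DP") < 10),
        ("qual<30", _col("QUAL") < 30),
        ("qd<1.5", _col("QD") < 1.5),
        ("fs>200", _col("FS") > 200),
    ]
    for rule, mask in checks:
        for i in np.flatnonzero(mask):  # NaN comparisons are False: missing never fires
            fired[i].append(rule)

    out = pd.DataFrame(index=df.index)
    out["low_quality"] = [bool(r) for r in fired]
    out["rules"] = [";".join(r) for r in fired]
    return out


# ---------------------------------------------------------------------------
# Pathogenicity / frequency filters

@dataclass(frozen=True)
class FilterThresholds:
    """Pathogenicity and frequency filter cutoffs.

    Boundaries follow the conventions of the annotation tools: PolyPhen-2
    HDIV calls a change damaging at >= 0.957 (inclusive), SIFT damaging at
    < 0.05, CADD Phred > 10, ExAC minor-allele frequency < 0.05.
    """

    min_coverage: int = 10
    min_polyphen: float = 0.957
    max_sift: float = 0.05
    min_cadd: float = 10.0
    max_maf: float = 0.05


def filter_pathogenic(variant: pd.Series, thresholds: FilterThresholds = FilterThresholds()) -> bool:
    """True iff the variant passes all coverage/pathogenicity/frequency filters.

    A missing annotation fails its criterion (conservative: un-annotated
    variants, e.g. splice/intronic, never pass).
    """
    def _num(key):
        v = variant.get(key)
        return None if v is None or pd.isna(v) else float(v)

    dp = _num("DP")
    pp = _num("Polyphen2_HDIV_score")
    sift = _num("SIFT_score")
    cadd = _num("CADD_phred")
    maf = _num("ExAC_ALL")
    t = thresholds
    return (
        dp is not None and dp >= t.min_coverage
        and pp is not None and pp >= t.min_polyphen
        and sift is not None and sift < t.max_sift
        and cadd is not None and cadd > t.min_cadd
        and maf is not None and maf < t.max_maf
    )


def pathogenic_mask(df: pd.DataFrame, thresholds: FilterThresholds = FilterThresholds()) -> pd.Series:
    """Vectorised :func:`filter_pathogenic` over a table (NaN fails its criterion)."""
    t = thresholds

    def _col(name):
        if name in df.columns:
            return pd.to_numeric(df[name], errors="coerce")
        return pd.Series(np.nan, index=df.index)

    return (
        (_col("DP") >= t.min_coverage)
        & (_col("Polyphen2_HDIV_score") >= t.min_polyphen)
        & (_col("SIFT_score") < t.max_sift)
        & (_col("CADD_phred") > t.min_cadd)
        & (_col("ExAC_ALL") < t.max_maf)
    )


# ---------------------------------------------------------------------------
# Genotype association

@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p: float
    method: str  # trend | trend_pca_adjusted | allelic_fisher


def trend_test(
    case_counts: Sequence[int], control_counts: Sequence[int]
) -> AssociationResult:
    """Cochran–Armitage trend test on genotype count triples (dose weights 0, 1, 2).

    Uses the correlation form chi2 = (N - 1) * r^2 with r the Pearson
    correlation between allele dose and case status, referred to a
    chi-square(1) null (the Armitage trend statistic in the normalisation
    used by EIGENSTRAT, so that the PCA-adjusted test with zero components
    reduces exactly to this one).  A monomorphic variant returns statistic 0,
    p = 1.
    """
    r0, r1, r2 = (int(c) for c in case_counts)
    s0, s1, s2 = (int(c) for c in control_counts)
    if min(r0, r1, r2, s0, s1, s2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    R, S = r0 + r1 + r2, s0 + s1 + s2
    if R == 0 or S == 0:
        raise ValueError("need at least one case and one control with a genotype")
    N = R + S
    n1 = r1 + s1
    n2 = r2 + s2
    # moments of dose g and indicator y
    mg = (n1 + 2 * n2) / N
    vg = (n1 + 4 * n2) / N - mg * mg
    my = R / N
    vy = my * (1 - my)
    if vg <= 0 or vy <= 0:
        return AssociationResult(0.0, 1.0, "trend")
    cov = (r1 + 2 * r2) / N - mg * my
    r = cov / np.sqrt(vg * vy)
    chi2 = (N - 1) * r * r
    p = float(stats.chi2.sf(chi2, df=1))
    return AssociationResult(float(chi2), p, "trend")


def allelic_fisher_test(
    case_counts: Sequence[int], control_counts: Sequence[int]
) -> AssociationResult:
    """Two-sided Fisher exact test on the 2x2 allele-count table (fallback for tiny cohorts)."""
    r0, r1, r2 = case_counts
    s0, s1, s2 = control_counts
    table = [[r1 + 2 * r2, 2 * r0 + r1], [s1 + 2 * s2, 2 * s0 + s1]]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return AssociationResult(float(odds), float(p), "allelic_fisher")


def _impute_and_scale(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean-impute missing genotypes per variant, centre, and scale by sqrt(p(1-p)).

    Returns ``(scaled, centered)`` where ``centered`` is the mean-imputed,
    centred (unscaled) dose matrix used for the association statistics and
    ``scaled`` is the frequency-normalised matrix used for PCA.
    """
    G = np.asarray(G, dtype=float)
    col_mean = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    filled = np.where(np.isnan(G), col_mean[None, :], G)
    centered = filled - col_mean[None, :]
    p_hat = np.clip(col_mean / 2.0, 1e-12, 1 - 1e-12)
    scale = np.sqrt(p_hat * (1 - p_hat))
    scaled = centered / scale[None, :]
    return scaled, centered


def pca_adjust(
    G: np.ndarray, phenotype: np.ndarray, n_pcs: int
) -> tuple[np.ndarray, np.ndarray]:
    """Residualise genotypes and phenotype on the top genotype principal components.

    ``G`` is samples x variants with alternate-allele doses (NaN = missing);
    missing values are mean-imputed per variant before PCA, columns are
    centred and scaled by sqrt(p(1-p)).  The top ``n_pcs`` principal axes over
    samples are regressed out of every (centred, unscaled) genotype column and
    out of the centred case/control indicator.

    Returns ``(G_resid, y_resid)``.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = G.shape[0]
    if n_pcs < 0:
        raise ValueError("n_pcs must be >= 0")
    if n_pcs >= n:
        raise ValueError(f"n_pcs={n_pcs} must be smaller than the number of samples {n}")
    scaled, centered = _impute_and_scale(G)
    y_c = y - y.mean()
    if n_pcs == 0:
        return centered, y_c
    # principal axes over samples: left singular vectors of the scaled matrix
    U, s, _ = np.linalg.svd(scaled, full_matrices=False)
    k = min(n_pcs, int(np.sum(s > 1e-10)))
    Uk = U[:, :k]
    G_resid = centered - Uk @ (Uk.T @ centered)
    y_resid = y_c - Uk @ (Uk.T @ y_c)
    return G_resid, y_resid


def trend_scan(
    G: np.ndarray, phenotype: np.ndarray, n_pcs: int = 0
) -> pd.DataFrame:
    """Per-variant trend chi-square and p, optionally PCA-adjusted.

    With ``n_pcs = 0`` this is the plain Cochran–Armitage trend test in
    correlation form, chi2 = (N-1) r^2; with ``n_pcs = K > 0`` the statistic
    is (N-K-1) r^2 on the residualised doses and phenotype, each referred to
    a chi-square(1) null.

    Returns a DataFrame with columns ``statistic``, ``p``, ``method``.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = G.shape[0]
    G_r, y_r = pca_adjust(G, y, n_pcs)
    denom_df = n - n_pcs - 1
    gg = np.einsum("ij,ij->j", G_r, G_r)
    yy = float(y_r @ y_r)
    gy = y_r @ G_r
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where((gg > 1e-24) & (yy > 1e-24), (gy * gy) / (gg * yy), 0.0)
    chi2 = denom_df * r2
    p = stats.chi2.sf(chi2, df=1)
    method = "trend" if n_pcs == 0 else "trend_pca_adjusted"
    return pd.DataFrame({"statistic": chi2, "p": p, "method": method})


def genotype_matrix(
    df: pd.DataFrame, sample_ids: Sequence[str]
) -> np.ndarray:
    """Extract the samples x variants dose matrix from a variant table.

    Genotype columns are named by sample id; non-numeric / missing entries
    become NaN.
    """
    missing = [s for s in sample_ids if s not in df.columns]
    if missing:
        raise KeyError(f"variant table lacks genotype column(s): {missing}")
    cols = [pd.to_numeric(df[s], errors="coerce").to_numpy(dtype=float) for s in sample_ids]
    return np.vstack(cols)  # samples x variants


def associate(
    df: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    method: str = "trend_pca_adjusted",
    n_pcs: int = 10,
) -> pd.DataFrame:
    """Case/control association for every variant row of ``df``.

    ``method`` is one of ``trend``, ``trend_pca_adjusted`` (default, with
    ``n_pcs`` genotype principal components regressed out), or
    ``allelic_fisher``.
    """
    samples = list(sample_sheet["sample_id"])
    y = (sample_sheet["group"].to_numpy() == "case").astype(float)
    G = genotype_matrix(df, samples)  # samples x variants
    if method == "trend":
        res = trend_scan(G, y, n_pcs=0)
    elif method == "trend_pca_adjusted":
        k = min(n_pcs, max(0, len(samples) - 2))
        res = trend_scan(G, y, n_pcs=k)
    elif method == "allelic_fisher":
        rows = []
        case_mask = y == 1
        for j in range(G.shape[1]):
            g = G[:, j]
            counts = []
            for mask in (case_mask, ~case_mask):
                gg = g[mask]
                counts.append([int(np.nansum(gg == k)) for k in (0, 1, 2)])
            rows.append(allelic_fisher_test(counts[0], counts[1]))
        res = pd.DataFrame(
            {"statistic": [r.statistic for r in rows], "p": [r.p for r in rows],
             "method": "allelic_fisher"}
        )
    else:
        raise ValueError(f"unknown association method: {method!r}")
    res.index = df.index
    return res


# ---------------------------------------------------------------------------
# Seed-gene selection

@dataclass(frozen=True)
class SampleSeedSet:
    """A sample's ranked seed genes (ascending best p-value, alphabetical ties)."""

    sample_id: str
    group: str
    seeds: tuple[str, ...]
    pvalues: tuple[float, ...] = field(default=())

    def __len__(self) -> int:
        return len(self.seeds)


def select_seed_genes(
    sample_id: str,
    group: str,
    df: pd.DataFrame,
    pvalues: pd.Series,
    K: int = 30,
) -> SampleSeedSet:
    """Top-``K`` genes for one sample, ranked by its most significant variant per gene.

    A variant counts toward the sample iff the sample carries at least one
    alternate allele there.  The gene's p-value is the minimum over the
    sample's qualifying variants in that gene; ties break alphabetically by
    symbol for reproducibility.  The input ``df`` must already be QC-passed
    and pathogenicity-filtered.
    """
    if sample_id not in df.columns:
        raise KeyError(f"no genotype column for sample {sample_id!r}")
    dose = pd.to_numeric(df[sample_id], errors="coerce")
    carried = df.loc[(dose >= 1).fillna(False)]
    if carried.empty:
        logger.warning("sample %s has no qualifying variants; empty seed set", sample_id)
        return SampleSeedSet(sample_id, group, (), ())
    per_gene = (
        pd.DataFrame({"gene": carried["Gene"].astype(str).str.upper(),
                      "p": pvalues.loc[carried.index].to_numpy(dtype=float)})
        .groupby("gene", sort=False)["p"].min()
        .reset_index()
        .sort_values(["p", "gene"], kind="stable")
        .head(K)
    )
    return SampleSeedSet(
        sample_id, group,
        tuple(per_gene["gene"]), tuple(float(p) for p in per_gene["p"]),
    )


def seed_sets_from_variants(
    df: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    thresholds: FilterThresholds = FilterThresholds(),
    K: int = 30,
    method: str = "trend_pca_adjusted",
    n_pcs: int = 10,
) -> tuple[list[SampleSeedSet], dict]:
    """Full variant stage: QC flags -> pathogenicity filter -> association -> seeds.

    Returns the per-sample seed sets (sample-sheet order) and a dict of stage
    counts for the run summary.
    """
    flags = low_quality_flags(df)
    clean = df.loc[~flags["low_quality"]]
    keep = pathogenic_mask(clean, thresholds)
    filtered = clean.loc[keep]
    counts = {
        "variants_total": int(len(df)),
        "variants_low_quality": int(flags["low_quality"].sum()),
        "variants_pass_filters": int(len(filtered)),
    }
    if filtered.empty:
        logger.warning("no variants survive QC + pathogenicity filters")
        return (
            [SampleSeedSet(r.sample_id, r.group, (), ())
             for r in sample_sheet.itertuples()],
            counts,
        )
    assoc = associate(filtered, sample_sheet, method=method, n_pcs=n_pcs)
    seed_sets = [
        select_seed_genes(r.sample_id, r.group, filtered, assoc["p"], K=K)
        for r in sample_sheet.itertuples()
    ]
    counts["samples_with_seeds"] = int(sum(1 for s in seed_sets if len(s)))
    return seed_sets, counts
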