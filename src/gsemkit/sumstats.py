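"""Reading, harmonizing and quality-filtering GWAS summary statistics.

The entry point of every analysis is a set of per-trait GWAS summary
statistics files.  Before any genetic-covariance estimation these are
"munged": restricted to a reference SNP panel (HapMap3-style), aligned so
that every trait's Z-statistic is signed with respect to the same reference
allele, and filtered on imputation quality and minor allele frequency.
Strand-ambiguous variants (A/T and C/G pairs) are removed because their
orientation cannot be resolved without allele frequencies.
"""

from __future__ import annotations

import gzip
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class ConfigurationError(ValueError):
    """A column mapping or threshold is unusable."""


class InputError(ValueError):
    """The input data cannot support the requested computation."""


@dataclass
class ReferencePanel:
    """Reference SNP list with alleles and positions.

    ``table`` has columns SNP, CHR, BP, A1, A2; snp ids are unique, alleles
    are single bases and A1 != A2 per record.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"SNP", "CHR", "BP", "A1", "A2"}
        missing = required - set(self.table.columns)
        if missing:
            raise ConfigurationError(f"reference panel missing columns: {sorted(missing)}")
        if self.table["SNP"].duplicated().any():
            raise InputError("reference panel contains duplicate snp ids")
        if (self.table["A1"] == self.table["A2"]).any():
            raise InputError("reference panel record with identical alleles")
        if (self.table["BP"] <= 0).any():
            raise InputError("reference panel positions must be positive")

    def __len__(self) -> int:
        return len(self.table)

    @classmethod
    def from_file(cls, path: str | Path) -> "ReferencePanel":
        """Read a 5-column whitespace-delimited panel file (SNP CHR BP A1 A2)."""
        df = pd.read_csv(path, sep=r"\s+")
        return cls(df[["SNP", "CHR", "BP", "A1", "A2"]])


@dataclass
class RawSumstats:
    """Parsed but not yet harmonized summary statistics for one trait.

    ``table`` columns (canonical names): SNP, A1 (effect allele), A2
    (other allele), and a sufficient subset of Z, BETA, SE, P, N, INFO, EAF,
    CHR, BP.  Each row must allow a Z to be computed: either Z directly,
    BETA with SE, or a signed BETA with P.
    """

    trait_name: str
    table: pd.DataFrame
    n_dropped_parse: int = 0


@dataclass
class MungedTrait:
    """Reference-aligned, QC-filtered Z statistics ready for LD score regression.

    The sign of Z is with respect to the panel's A1 allele.  ``binary`` traits
    carry the sample prevalence P (0.5 for meta-analysed case-control traits
    analysed on effective N, to correct ascertainment) and population
    prevalence K for later liability-scale conversion.
    """

    trait_name: str
    table: pd.DataFrame  # columns SNP, Z, N
    binary: bool = False
    sample_prev: float | None = None
    pop_prev: float | None = None
    qc_report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)

    def write(self, path: str | Path) -> None:
        """Write as tab-delimited SNP Z N, with a JSON QC report next to it."""
        path = Path(path)
        self.table.to_csv(path, sep="\t", index=False)
        if self.qc_report:
            path.with_suffix(path.suffix + ".qc.json").write_text(
                json.dumps(self.qc_report, indent=2, sort_keys=True)
            )

    @classmethod
    def read(cls, path: str | Path, trait_name: str | None = None, **kw) -> "MungedTrait":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        return cls(trait_name or path.stem, df[["SNP", "Z", "N"]], **kw)


_MANDATORY_ALWAYS = ("snp", "effect_allele", "other_allele")

# canonical name -> column-map keys
_OPTIONAL = ("z", "beta", "se", "p", "n", "info", "eaf", "chr", "bp")


def parse_sumstats(
    path: str | Path,
    column_map: dict[str, str],
    trait_name: str | None = None,
    n_default: float | None = None,
) -> RawSumstats:
    """Parse a delimited summary-statistics file into canonical columns.

    ``column_map`` maps canonical keys (snp, effect_allele, other_allele, z,
    beta, se, p, n, info, eaf, chr, bp) to the file's header names.  Rows
    whose mandatory fields fail to parse are dropped and counted.  When the
    file carries no per-SNP N, ``n_default`` (study-level N) is broadcast.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep=r"\s+")
    if df.empty:
        raise InputError(f"{path}: empty sumstats file")

    for key in _MANDATORY_ALWAYS:
        col = column_map.get(key)
        if col is None or col not in df.columns:
            raise ConfigurationError(f"column map does not resolve mandatory column {key!r}")

    out = pd.DataFrame({"SNP": df[column_map["snp"]].astype(str)})
    out["A1"] = df[column_map["effect_allele"]].astype(str).str.upper()
    out["A2"] = df[column_map["other_allele"]].astype(str).str.upper()
    for key, canon in (("z", "Z"), ("beta", "BETA"), ("se", "SE"), ("p", "P"),
                       ("n", "N"), ("info", "INFO"), ("eaf", "EAF"),
                       ("chr", "CHR"), ("bp", "BP")):
        col = column_map.get(key)
        if col is not None and col in df.columns:
            out[canon] = pd.to_numeric(df[col], errors="coerce")

    has_z = "Z" in out.columns
    has_beta_se = "BETA" in out.columns and "SE" in out.columns
    has_beta_p = "BETA" in out.columns and "P" in out.columns
    if not (has_z or has_beta_se or has_beta_p):
        raise ConfigurationError(
            "column map must resolve a signed statistic: Z, or BETA+SE, or BETA+P"
        )
    if "N" not in out.columns:
        if n_default is None:
            raise ConfigurationError("no N column mapped and no n_default supplied")
        out["N"] = float(n_default)
    else:
        out["N"] = out["N"].fillna(n_default if n_default is not None else np.nan)

    # a row is usable if it can yield a Z and has a positive N
    ok = out["SNP"].notna() & out["N"].notna() & (out["N"] > 0)
    stat_ok = pd.Series(False, index=out.index)
    if has_z:
        stat_ok |= out["Z"].notna()
    if has_beta_se:
        stat_ok |= out["BETA"].notna() & out["SE"].notna() & (out["SE"] > 0)
    if has_beta_p:
        stat_ok |= out["BETA"].notna() & out["P"].notna() & (out["P"] > 0) & (out["P"] <= 1)
    ok &= stat_ok
    n_dropped = int((~ok).sum())
    if n_dropped:
        logger.info("%s: dropped %d unparseable rows", path, n_dropped)
    out = out[ok].reset_index(drop=True)
    return RawSumstats(trait_name or path.stem, out, n_dropped_parse=n_dropped)


def _compute_z(df: pd.DataFrame) -> np.ndarray:
    """Z from the best available source: Z column, beta/SE, or signed beta + p."""
    z = np.full(len(df), np.nan)
    if "Z" in df.columns:
        z = df["Z"].to_numpy(dtype=float, copy=True)
    need = np.isnan(z)
    if need.any() and "BETA" in df.columns and "SE" in df.columns:
        beta = df["BETA"].to_numpy(dtype=float)
        se = df["SE"].to_numpy(dtype=float)
        use = need & np.isfinite(beta) & np.isfinite(se) & (se > 0)
        z[use] = beta[use] / se[use]
        need = np.isnan(z)
    if need.any() and "BETA" in df.columns and "P" in df.columns:
        beta = df["BETA"].to_numpy(dtype=float)
        p = df["P"].to_numpy(dtype=float)
        use = need & np.isfinite(beta) & np.isfinite(p) & (p > 0) & (p <= 1)
        z[use] = np.sign(beta[use]) * stats.norm.isf(p[use] / 2.0)
    return z


def munge(
    raw: RawSumstats,
    panel: ReferencePanel,
    min_info: float = 0.9,
    min_maf: float = 0.01,
    binary: bool = False,
    sample_prev: float | None = None,
    pop_prev: float | None = None,
) -> MungedTrait:
    """Harmonize one trait against the reference panel.

    Keeps only panel SNPs; drops poorly imputed SNPs (INFO < ``min_info``),
    rare SNPs (MAF < ``min_maf``), strand-ambiguous variants and allele
    mismatches; flips the Z sign where the effect allele matches the panel's
    A2 (directly or after strand complement); deduplicates on first
    occurrence.  Returns a :class:`MungedTrait` whose qc_report counts the
    drops per filter.
    """
    if not (0 <= min_info <= 1) or not (0 <= min_maf <= 1):
        raise ConfigurationError("min_info and min_maf must lie in [0, 1]")
    df = raw.table.copy()
    report: dict[str, int] = {"input": len(df)}

    dup = df["SNP"].duplicated(keep="first")
    report["duplicate"] = int(dup.sum())
    if dup.any():
        logger.info("%s: dropping %d duplicate snp ids", raw.trait_name, int(dup.sum()))
        df = df[~dup]

    panel_t = panel.table.set_index("SNP")
    in_panel = df["SNP"].isin(panel_t.index)
    report["not_in_panel"] = int((~in_panel).sum())
    df = df[in_panel]

    if "INFO" in df.columns:
        bad = df["INFO"].notna() & (df["INFO"] < min_info)
        report["low_info"] = int(bad.sum())
        df = df[~bad]
    else:
        report["low_info"] = 0
    if "EAF" in df.columns:
        maf = np.minimum(df["EAF"], 1.0 - df["EAF"])
        bad = maf.notna() & (maf < min_maf)
        report["low_maf"] = int(bad.sum())
        df = df[~bad]
    else:
        report["low_maf"] = 0

    a1 = df["A1"].to_numpy()
    a2 = df["A2"].to_numpy()
    valid_bases = np.isin(a1, list(_COMPLEMENT)) & np.isin(a2, list(_COMPLEMENT))
    amb_mask = np.array([
        (x, y) in _AMBIGUOUS_PAIRS if vb else False
        for x, y, vb in zip(a1, a2, valid_bases)
    ], dtype=bool)
    report["strand_ambiguous"] = int(amb_mask.sum())
    keep = valid_bases & ~amb_mask
    report["invalid_alleles"] = int((~valid_bases).sum())
    df = df[keep]

    pa1 = panel_t.loc[df["SNP"], "A1"].to_numpy()
    pa2 = panel_t.loc[df["SNP"], "A2"].to_numpy()
    a1 = df["A1"].to_numpy()
    a2 = df["A2"].to_numpy()
    c1 = np.array([_COMPLEMENT[x] for x in a1])
    c2 = np.array([_COMPLEMENT[x] for x in a2])

    same = (a1 == pa1) & (a2 == pa2)
    flip = (a1 == pa2) & (a2 == pa1)
    same_c = (c1 == pa1) & (c2 == pa2)
    flip_c = (c1 == pa2) & (c2 == pa1)
    match = same | flip | same_c | flip_c
    report["allele_mismatch"] = int((~match).sum())
    df = df[match]
    sign = np.where((flip | flip_c)[match], -1.0, 1.0)

    z = _compute_z(df) * sign
    out = pd.DataFrame({"SNP": df["SNP"].to_numpy(), "Z": z, "N": df["N"].to_numpy(dtype=float)})
    out = out[np.isfinite(out["Z"])].reset_index(drop=True)
    report["retained"] = len(out)

    if len(out) == 0:
        raise InputError(f"{raw.trait_name}: no SNPs retained after munging")
    if len(out) < 0.1 * len(panel):
        logger.warning(
            "%s: only %d of %d panel SNPs retained (<10%%)",
            raw.trait_name, len(out), len(panel),
        )
    return MungedTrait(
        raw.trait_name, out,
        binary=binary, sample_prev=sample_prev, pop_prev=pop_prev,
        qc_report=report,
    )


def effective_n(cases: float, controls: float) -> float:
    """Effective sample size 4 / (1/cases + 1/controls) for one cohort.

    For meta-analyses, apply per cohort and sum (see :func:`sum_effective_n`).
    """
    if cases <= 0 or controls <= 0:
        raise InputError("cases and controls must be positive")
    return 4.0 / (1.0 / cases + 1.0 / controls)


def sum_effective_n(cohorts: list[tuple[float, float]]) -> float:
    """Sum of per-cohort effective sample sizes for a meta-analysis."""
    return float(sum(effective_n(ca, co) for ca, co in cohorts))
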