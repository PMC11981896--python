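"""Bayesian colocalization of two traits at a genomic locus.

For each locus (all variants within a 1-Mb window of a lead variant) the
method computes per-SNP approximate Bayes factors for association with each
trait under a normal effect-size prior N(0, W), and combines them with
per-SNP priors into posterior probabilities of five hypotheses:

    H0  no association with either trait
    H1  association with trait 1 only
    H2  association with trait 2 only
    H3  both traits, two distinct causal variants
    H4  both traits, one shared causal variant

assuming at most one causal variant per trait in the locus.  A posterior
of at least 0.75 for H4 is called colocalization (shared causal variant);
for H3, pleiotropy driven by distinct variants.  Default per-SNP priors are
p1 = p2 = 1e-4 and p12 = 1e-5.  All hypothesis masses are accumulated in
log space so large Z-scores cannot overflow.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .sumstats import InputError, MungedTrait, ReferencePanel

__all__ = [
    "ColocPriors", "LocusData", "ColocResult", "GenomicRegion",
    "define_loci", "wakefield_abf", "log_abf", "coloc_posteriors",
    "ld_proxy", "exclude_region", "estimate_sdY",
]


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association (p1, p2) and of a shared
    causal variant (p12)."""

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        for name, v in (("p1", self.p1), ("p2", self.p2), ("p12", self.p12)):
            if not (0 < v < 1):
                raise InputError(f"{name} must lie strictly in (0, 1)")
        if self.p12 > min(self.p1, self.p2):
            raise InputError("p12 must not exceed min(p1, p2)")


@dataclass(frozen=True)
class GenomicRegion:
    """1-based closed interval on one chromosome."""

    chromosome: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise InputError("region end before start")


@dataclass
class LocusData:
    """Per-SNP effect summaries for two traits inside one window.

    ``trait1``/``trait2`` carry columns SNP, BETA, VARBETA (= SE^2), MAF, N;
    ``binary1``/``binary2`` select the effect-size prior (log-odds vs
    quantitative scale).  The SNP lists are intersected at analysis time.
    """

    locus_id: str
    chromosome: int
    window: tuple[int, int]
    lead_snp: str
    trait1: pd.DataFrame
    trait2: pd.DataFrame
    binary1: bool = True
    binary2: bool = True


@dataclass
class ColocResult:
    """Posterior probabilities of H0..H4 and the categorical call."""

    pph: np.ndarray  # length 5, sums to 1
    n_snps: int
    call: str
    locus_id: str = ""

    @property
    def pph0(self) -> float: return float(self.pph[0])
    @property
    def pph1(self) -> float: return float(self.pph[1])
    @property
    def pph2(self) -> float: return float(self.pph[2])
    @property
    def pph3(self) -> float: return float(self.pph[3])
    @property
    def pph4(self) -> float: return float(self.pph[4])


def define_loci(table: pd.DataFrame, p_threshold: float = 5e-8,
                merge_distance: int = 250_000, half_window: int = 500_000,
                ) -> list[tuple[str, GenomicRegion]]:
    """Greedy clumping of genome-wide-significant SNPs into risk loci.

    ``table`` needs columns SNP, CHR, BP, P.  Repeatedly the most significant
    unassigned SNP below ``p_threshold`` becomes a lead; significant SNPs on
    the same chromosome within ``merge_distance`` of its locus are merged
    into it.  Each locus window is lead position +/- ``half_window`` (1 Mb
    total by default).  Returns [] when nothing reaches the threshold.
    """
    sig = table.loc[table["P"] < p_threshold, ["SNP", "CHR", "BP", "P"]].copy()
    if sig.empty:
        return []
    sig = sig.sort_values(["P", "SNP"], kind="mergesort").reset_index(drop=True)
    assigned = np.zeros(len(sig), dtype=bool)
    loci: list[tuple[str, GenomicRegion]] = []
    for i in range(len(sig)):
        if assigned[i]:
            continue
        lead = sig.iloc[i]
        assigned[i] = True
        lo = hi = int(lead["BP"])
        # absorb significant SNPs within merge_distance of the growing locus
        changed = True
        while changed:
            changed = False
            cand = (~assigned) & (sig["CHR"] == lead["CHR"]).to_numpy() \
                   & (sig["BP"].to_numpy() >= lo - merge_distance) \
                   & (sig["BP"].to_numpy() <= hi + merge_distance)
            if cand.any():
                assigned |= cand
                lo = min(lo, int(sig.loc[cand, "BP"].min()))
                hi = max(hi, int(sig.loc[cand, "BP"].max()))
                changed = True
        region = GenomicRegion(int(lead["CHR"]),
                               max(1, int(lead["BP"]) - half_window),
                               int(lead["BP"]) + half_window)
        loci.append((str(lead["SNP"]), region))
    return loci


def wakefield_abf(beta: float, varbeta: float, W: float) -> float:
    """Approximate Bayes factor for one SNP under an N(0, W) effect prior.

    With z = beta/sqrt(varbeta) and shrinkage r = W/(W + varbeta), the ABF is
    sqrt(1 - r) * exp(z^2 r / 2); W -> 0 gives 1 (no evidence either way).
    """
    return float(np.exp(log_abf(np.asarray([beta]), np.asarray([varbeta]), W)[0]))


def log_abf(beta: np.ndarray, varbeta: np.ndarray, W: float) -> np.ndarray:
    """Vectorized log approximate Bayes factors."""
    beta = np.asarray(beta, dtype=float)
    varbeta = np.asarray(varbeta, dtype=float)
    if np.any(varbeta <= 0):
        raise InputError("varbeta must be strictly positive")
    if W < 0:
        raise InputError("prior variance W must be non-negative")
    r = W / (W + varbeta)
    z2 = beta ** 2 / varbeta
    return 0.5 * np.log1p(-r) + 0.5 * z2 * r


def estimate_sdY(varbeta: np.ndarray, maf: np.ndarray, n: np.ndarray) -> float:
    """Trait standard deviation from varbeta ~ sdY^2 / (2 maf (1-maf) n).

    Regression through the origin of 2 maf (1-maf) n on 1/varbeta gives
    sdY^2 (the convention of the colocalization literature).
    """
    oneover = 1.0 / np.asarray(varbeta, dtype=float)
    nvx = 2.0 * np.asarray(n, dtype=float) * maf * (1.0 - maf)
    sd2 = float(np.sum(nvx * oneover) / np.sum(oneover ** 2))
    if sd2 <= 0:
        raise InputError("non-positive sdY^2 estimate; check varbeta/maf/n")
    return float(np.sqrt(sd2))


def _prior_W(df: pd.DataFrame, binary: bool) -> float:
    """Effect-size prior variance: (0.2)^2 on the log-odds scale for binary
    traits, (0.15 sdY)^2 for quantitative traits."""
    if binary:
        return 0.2 ** 2
    sdY = estimate_sdY(df["VARBETA"].to_numpy(), df["MAF"].to_numpy(),
                       df["N"].to_numpy())
    return (0.15 * sdY) ** 2


def coloc_posteriors(locus: LocusData, priors: ColocPriors = ColocPriors(),
                     pph_threshold: float = 0.75,
                     W1: float | None = None, W2: float | None = None) -> ColocResult:
    """Posterior hypothesis probabilities for one locus.

    Unnormalized masses (log space): H0 = 1, H1 = p1 * sum(ABF1),
    H2 = p2 * sum(ABF2), H3 = p1 p2 * (sum(ABF1) sum(ABF2) - sum(ABF1*ABF2)),
    H4 = p12 * sum(ABF1*ABF2).  A single-SNP locus has exactly zero H3 mass
    (no two-distinct-variant configuration exists).
    """
    merged = locus.trait1.merge(locus.trait2, on="SNP", suffixes=("_1", "_2"))
    if merged.empty:
        raise InputError(f"locus {locus.locus_id}: no shared SNPs between traits")
    n_snps = len(merged)
    if W1 is None:
        W1 = _prior_W(locus.trait1, locus.binary1)
    if W2 is None:
        W2 = _prior_W(locus.trait2, locus.binary2)
    l1 = log_abf(merged["BETA_1"].to_numpy(), merged["VARBETA_1"].to_numpy(), W1)
    l2 = log_abf(merged["BETA_2"].to_numpy(), merged["VARBETA_2"].to_numpy(), W2)

    ls1 = logsumexp(l1)
    ls2 = logsumexp(l2)
    ls12 = logsumexp(l1 + l2)
    logs = np.empty(5)
    logs[0] = 0.0
    logs[1] = np.log(priors.p1) + ls1
    logs[2] = np.log(priors.p2) + ls2
    if n_snps == 1:
        logs[3] = -np.inf
    else:
        # log(sum_i sum_{j != i} ABF1_i ABF2_j) = log(e^{ls1+ls2} - e^{ls12})
        diff = ls12 - (ls1 + ls2)
        logs[3] = (np.log(priors.p1) + np.log(priors.p2) + ls1 + ls2
                   + (np.log1p(-np.exp(diff)) if diff < -1e-15 else -np.inf))
    logs[4] = np.log(priors.p12) + ls12
    pph = np.exp(logs - logsumexp(logs))
    pph /= pph.sum()

    if pph[4] >= pph_threshold:
        call = "colocalized"
    elif pph[3] >= pph_threshold:
        call = "distinct_variants"
    elif pph[1] >= pph_threshold or pph[2] >= pph_threshold:
        call = "single_trait"
    elif pph[0] >= pph_threshold:
        call = "no_association"
    else:
        call = "inconclusive"
    return ColocResult(pph=pph, n_snps=n_snps, call=call, locus_id=locus.locus_id)


def ld_proxy(lead: str, candidates: list[tuple[str, float]],
             available: set[str], min_r2: float = 0.8) -> str | None:
    """Substitute a lead SNP missing from one trait by its best LD proxy.

    ``candidates`` are (snp_id, r2-to-lead) from a reference LD table;
    ``available`` is the set of SNPs present in both traits.  Returns the
    lead itself when usable, else the available candidate with the highest
    r2 >= ``min_r2``, else None (locus not analysable).
    """
    if lead in available:
        return lead
    usable = [(snp, r2) for snp, r2 in candidates
              if snp in available and r2 >= min_r2]
    if not usable:
        return None
    return max(usable, key=lambda t: (t[1], t[0]))[0]


def exclude_region(traits: list[MungedTrait], region: GenomicRegion,
                   panel: ReferencePanel) -> list[MungedTrait]:
    """Remove all SNPs inside a closed genomic interval from every trait.

    Positions come from the reference panel.  Downstream LDSC and model
    comparisons can then be rerun on the filtered traits to test whether a
    genetic correlation is driven by a single region.
    """
    ptab = panel.table
    in_region = ptab.loc[
        (ptab["CHR"] == region.chromosome)
        & (ptab["BP"] >= region.start) & (ptab["BP"] <= region.end), "SNP"
    ]
    drop = set(in_region)
    if not drop:
        import logging
        logging.getLogger(__name__).warning(
            "exclusion region %s covers no panel SNPs; traits unchanged", region)
        return traits
    out = []
    for t in traits:
        kept = t.table[~t.table["SNP"].isin(drop)].reset_index(drop=True)
        out.append(replace(t, table=kept))
    return out
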