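"""Synthetic GWAS summary statistics with LDSC moment structure.

Every estimation stage of the package assumes a specific statistical model;
this module generates data directly from those models, at desk scale, so
each stage is testable by parameter recovery without any external download.

Z-scores are generated at the summary level (no individual genotypes): for
SNP j the k-vector of trait Z-scores is multivariate normal with

    Cov[z_aj, z_bj] = sqrt(N_a N_b) cov_g(a,b) l_j / M + C0_ab,
    Var[z_aj]       = 1 + N_a h2_a l_j / M,

where C0_ab = (shared-sample fraction) x (phenotypic correlation) is the
sample-overlap term absorbed by the LDSC cross-trait intercept.  LD scores
are gamma distributed and SNPs are laid out on 22 autosomes in proportion
to real chromosome lengths, so odd/even-autosome splits are non-trivial.

Locus-level colocalization scenarios place causal variants per hypothesis
H0-H4 on an AR(1) LD correlation structure and propagate marginal effects
through the LD matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .coloc import GenomicRegion, LocusData
from .ldsc import LdScoreTable
from .sumstats import InputError, MungedTrait, ReferencePanel

__all__ = [
    "TraitSpec", "SyntheticTruth", "simulate_ld_scores", "simulate_sumstats",
    "simulate_coloc_locus", "embed_regional_signal", "make_panel",
    "factor_structure_R",
]

# GRCh37 autosome lengths (Mb) used to apportion synthetic SNPs
_CHR_MB = np.array([
    249.25, 243.20, 198.02, 191.15, 180.92, 171.12, 159.14, 146.36,
    141.21, 135.53, 135.01, 133.85, 115.17, 107.35, 102.53, 90.35,
    81.20, 78.08, 59.13, 63.03, 48.13, 51.30,
])


@dataclass
class TraitSpec:
    """Generating parameters for one synthetic trait."""

    name: str
    h2: float
    n: float
    binary: bool = False
    K: float | None = None  # population prevalence (binary)
    P: float | None = None  # sample prevalence (binary)

    def __post_init__(self) -> None:
        if not (0 <= self.h2 <= 1):
            raise InputError(f"{self.name}: h2 must lie in [0, 1]")
        if self.n <= 0:
            raise InputError(f"{self.name}: sample size must be positive")


@dataclass
class SyntheticTruth:
    """Complete generating configuration for a multi-trait study.

    ``R_true`` is the genetic correlation matrix (unit diagonal, PSD);
    ``overlap`` and ``pheno_corr`` give pairwise shared-sample fractions and
    phenotypic correlations (identity = no overlap).  A fixed seed makes the
    generated data bit-reproducible.
    """

    traits: list[TraitSpec]
    R_true: np.ndarray
    M: int = 20_000
    seed: int = 0
    overlap: np.ndarray | None = None
    pheno_corr: np.ndarray | None = None
    ld_mean: float = 100.0
    ld_shape: float = 3.0

    def __post_init__(self) -> None:
        k = len(self.traits)
        self.R_true = np.asarray(self.R_true, dtype=float)
        if self.R_true.shape != (k, k):
            raise InputError("R_true shape must match the number of traits")
        if not np.allclose(np.diag(self.R_true), 1.0):
            raise InputError("R_true must have unit diagonal")
        if np.linalg.eigvalsh((self.R_true + self.R_true.T) / 2).min() < -1e-8:
            raise InputError("R_true must be positive semi-definite")

    @property
    def k(self) -> int:
        return len(self.traits)

    @property
    def covg(self) -> np.ndarray:
        """Genetic covariance matrix implied by h2 values and R_true."""
        root_h2 = np.sqrt([t.h2 for t in self.traits])
        return self.R_true * np.outer(root_h2, root_h2)

    def to_yaml(self, path) -> None:
        doc = {
            "traits": [
                {"name": t.name, "h2": t.h2, "n": t.n, "binary": t.binary,
                 "K": t.K, "P": t.P} for t in self.traits
            ],
            "R_true": self.R_true.tolist(),
            "M": self.M, "seed": self.seed,
            "overlap": None if self.overlap is None else np.asarray(self.overlap).tolist(),
            "pheno_corr": None if self.pheno_corr is None else np.asarray(self.pheno_corr).tolist(),
            "ld_mean": self.ld_mean, "ld_shape": self.ld_shape,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        traits = [TraitSpec(**t) for t in doc["traits"]]
        return cls(
            traits=traits, R_true=np.asarray(doc["R_true"]),
            M=doc["M"], seed=doc["seed"],
            overlap=None if doc.get("overlap") is None else np.asarray(doc["overlap"]),
            pheno_corr=None if doc.get("pheno_corr") is None else np.asarray(doc["pheno_corr"]),
            ld_mean=doc.get("ld_mean", 100.0), ld_shape=doc.get("ld_shape", 3.0),
        )


def simulate_ld_scores(M: int, mean: float = 100.0, shape: float = 3.0,
                       seed: int = 0) -> LdScoreTable:
    """Gamma-distributed LD scores on a 22-autosome synthetic genome.

    SNP counts per chromosome are proportional to real autosome lengths and
    positions are evenly spaced, so chromosome-restricted subsets (odd/even
    autosomes, region exclusions) behave like they would on real data.
    """
    if M <= 0:
        raise InputError("M must be positive")
    rng = np.random.default_rng(seed)
    frac = _CHR_MB / _CHR_MB.sum()
    counts = np.floor(frac * M).astype(int)
    counts[: M - counts.sum()] += 1  # distribute the remainder
    chroms = np.repeat(np.arange(1, 23), counts)
    bp = np.concatenate([
        np.linspace(1, _CHR_MB[c] * 1e6, counts[c], dtype=int)
        for c in range(22)
    ])
    ell = rng.gamma(shape=shape, scale=mean / shape, size=M)
    table = pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(M)],
        "CHR": chroms, "BP": bp, "L2": ell,
    })
    return LdScoreTable(table, m_total=float(M))


def _overlap_matrix(truth: SyntheticTruth) -> np.ndarray:
    k = truth.k
    if truth.overlap is None:
        return np.eye(k)
    C0 = np.asarray(truth.overlap, dtype=float) * np.asarray(
        truth.pheno_corr if truth.pheno_corr is not None else np.ones((k, k)), dtype=float)
    np.fill_diagonal(C0, 1.0)
    return C0


def simulate_sumstats(truth: SyntheticTruth, ld: LdScoreTable) -> list[MungedTrait]:
    """Draw per-SNP multi-trait Z-scores under the LDSC moment model."""
    k = truth.k
    M = float(ld.m_total)
    ell = ld.table["L2"].to_numpy()
    m_snp = len(ell)
    N = np.array([t.n for t in truth.traits])
    C0 = _overlap_matrix(truth)
    covg = truth.covg
    C1 = np.sqrt(np.outer(N, N)) * covg / M

    sigma = C0[None, :, :] + ell[:, None, None] * C1[None, :, :]
    try:
        L = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError:
        eigs = np.linalg.eigvalsh(sigma)
        bad = int(np.argmin(eigs[:, 0]))
        raise InputError(
            f"per-SNP covariance not PSD at SNP {ld.table['SNP'].iloc[bad]}; "
            "check R_true / overlap consistency"
        ) from None
    rng = np.random.default_rng(truth.seed)
    eps = rng.standard_normal((m_snp, k))
    z = np.einsum("jab,jb->ja", L, eps)

    out = []
    for i, t in enumerate(truth.traits):
        table = pd.DataFrame({
            "SNP": ld.table["SNP"].to_numpy(),
            "Z": z[:, i],
            "N": np.full(m_snp, t.n, dtype=float),
        })
        out.append(MungedTrait(t.name, table, binary=t.binary,
                               sample_prev=t.P, pop_prev=t.K))
    return out


def make_panel(ld: LdScoreTable, seed: int = 0) -> ReferencePanel:
    """Reference panel matching a synthetic LD score table.

    Alleles are drawn from the strand-unambiguous pairs so that munging a
    written-out synthetic trait against this panel is lossless.
    """
    rng = np.random.default_rng(seed)
    pairs = np.array([("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                      ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")])
    pick = rng.integers(0, len(pairs), size=len(ld.table))
    table = ld.table[["SNP", "CHR", "BP"]].copy()
    table["A1"] = pairs[pick, 0]
    table["A2"] = pairs[pick, 1]
    return ReferencePanel(table)


# ---------------------------------------------------------------------------
# colocalization scenarios
# ---------------------------------------------------------------------------

_HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


def simulate_coloc_locus(hypothesis: str, n_snps: int = 200, ld_rho: float = 0.9,
                         causal_z: float = 8.0, n: float = 50_000,
                         seed: int = 0, chromosome: int = 1,
                         start: int = 1_000_000) -> LocusData:
    """One two-trait locus generated under a colocalization hypothesis.

    An AR(1) LD correlation matrix (rho^|i-j|) propagates the causal
    variant's standardized effect (``causal_z`` at the causal SNP) into the
    marginal Z-scores of both traits, plus correlated noise.  Causal
    placement: H0 none; H1/H2 one trait only; H3 two distinct SNPs in low LD
    (quarter points of the locus); H4 one shared SNP at the centre.  Traits
    are quantitative with unit trait SD; varbeta = 1/(2 maf (1-maf) n).
    """
    if hypothesis not in _HYPOTHESES:
        raise InputError(f"hypothesis must be one of {_HYPOTHESES}")
    if hypothesis == "H3" and n_snps < 2:
        raise InputError("H3 requires at least 2 SNPs")
    rng = np.random.default_rng(seed)
    idx = np.arange(n_snps)
    Sigma = ld_rho ** np.abs(idx[:, None] - idx[None, :])
    Lchol = np.linalg.cholesky(Sigma + 1e-10 * np.eye(n_snps))

    mid, q1, q3 = n_snps // 2, n_snps // 4, (3 * n_snps) // 4
    causal = {"H0": (None, None), "H1": (mid, None), "H2": (None, mid),
              "H3": (q1, q3), "H4": (mid, mid)}[hypothesis]

    maf = rng.uniform(0.05, 0.5, size=n_snps)
    varbeta = 1.0 / (2.0 * maf * (1.0 - maf) * n)
    positions = start + np.sort(rng.choice(900_000, size=n_snps, replace=False))
    snps = [f"loc{seed}_{i}" for i in range(n_snps)]

    frames = []
    for c in causal:
        mean = Sigma[:, c] * causal_z if c is not None else np.zeros(n_snps)
        z = mean + Lchol @ rng.standard_normal(n_snps)
        beta = z * np.sqrt(varbeta)
        frames.append(pd.DataFrame({
            "SNP": snps, "BP": positions, "BETA": beta,
            "VARBETA": varbeta, "MAF": maf, "N": float(n),
        }))
    lead = snps[mid]
    return LocusData(
        locus_id=f"{hypothesis}_seed{seed}", chromosome=chromosome,
        window=(int(positions.min()), int(positions.max())), lead_snp=lead,
        trait1=frames[0], trait2=frames[1], binary1=False, binary2=False,
    )


# ---------------------------------------------------------------------------
# regional signal embedding (for the region-exclusion experiment)
# ---------------------------------------------------------------------------

def embed_regional_signal(t1: MungedTrait, t2: MungedTrait, ld: LdScoreTable,
                          region: GenomicRegion, rg_target: float,
                          h2: tuple[float, float], seed: int = 0,
                          ) -> tuple[MungedTrait, MungedTrait]:
    """Re-draw the Z-scores of two traits inside one region so that their
    genome-wide genetic correlation is driven entirely by that region.

    ``rg_target`` is the genome-wide correlation the region should induce;
    the local per-SNP covariance is boosted by the inverse of the region's
    LD-score share, so small regions need a large local correlation.  If the
    implied local correlation would exceed 1 (covariance not PSD), an error
    reports the minimum region share required.
    """
    tab = ld.table
    in_region = ((tab["CHR"] == region.chromosome)
                 & (tab["BP"] >= region.start) & (tab["BP"] <= region.end))
    if not in_region.any():
        raise InputError("region contains no SNPs")
    ell = tab["L2"].to_numpy()
    share = float(ell[in_region.to_numpy()].sum() / ell.sum())
    h2a, h2b = h2
    cov_target = rg_target * np.sqrt(h2a * h2b)
    cov_local = cov_target / share
    max_local = np.sqrt(h2a * h2b)
    if abs(cov_local) > max_local:
        raise InputError(
            f"region too small: holds {share:.3%} of LD score mass but needs "
            f">= {abs(cov_target) / max_local:.3%} to carry rg = {rg_target}"
        )
    snps = tab.loc[in_region, "SNP"]
    M = float(ld.m_total)
    ell_r = ell[in_region.to_numpy()]
    rng = np.random.default_rng(seed)

    out = []
    zs = []
    for t, h2_t in ((t1, h2a), (t2, h2b)):
        t_tab = t.table.set_index("SNP")
        missing = set(snps) - set(t_tab.index)
        if missing:
            raise InputError(f"{t.trait_name}: region SNPs missing from trait")
        zs.append(t_tab)
    n1 = float(zs[0].loc[snps, "N"].iloc[0])
    n2 = float(zs[1].loc[snps, "N"].iloc[0])
    var1 = 1.0 + n1 * h2a * ell_r / M
    var2 = 1.0 + n2 * h2b * ell_r / M
    cov12 = np.sqrt(n1 * n2) * cov_local * ell_r / M
    # 2x2 draws per SNP via explicit Cholesky
    a = np.sqrt(var1)
    b = cov12 / a
    c = np.sqrt(np.maximum(var2 - b ** 2, 1e-12))
    e = rng.standard_normal((len(snps), 2))
    z1_new = a * e[:, 0]
    z2_new = b * e[:, 0] + c * e[:, 1]
    for t, znew in ((t1, z1_new), (t2, z2_new)):
        tt = t.table.copy()
        sel = tt["SNP"].isin(set(snps))
        tt.loc[sel, "Z"] = tt.loc[sel, "SNP"].map(dict(zip(snps, znew)))
        out.append(MungedTrait(t.trait_name, tt, binary=t.binary,
                               sample_prev=t.sample_prev, pop_prev=t.pop_prev))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# factor-structured truth
# ---------------------------------------------------------------------------

def factor_structure_R(loadings: np.ndarray, factor_corr: np.ndarray,
                       outcome_gamma: np.ndarray | None = None,
                       outcome_corr: float = 0.0) -> np.ndarray:
    """Genetic correlation matrix implied by a factor model.

    ``loadings`` (p x f) and ``factor_corr`` (f x f) give the risk-factor
    block L Phi L' with unit diagonal restored; ``outcome_gamma`` (2 x f)
    optionally appends two outcome traits whose correlations with the
    factors are the given gammas, so cor(risk_i, outcome) = L_i . gamma and
    cor(outcome1, outcome2) = ``outcome_corr``.  Raises if the result is not
    PSD (inconsistent truth).
    """
    L = np.asarray(loadings, dtype=float)
    Phi = np.asarray(factor_corr, dtype=float)
    p = L.shape[0]
    block = L @ Phi @ L.T
    if np.any(np.diag(block) > 1 + 1e-9):
        raise InputError("communalities exceed 1; loadings too large")
    R = block.copy()
    np.fill_diagonal(R, 1.0)
    if outcome_gamma is not None:
        G = np.asarray(outcome_gamma, dtype=float)
        cross = L @ G.T  # p x 2
        R = np.block([
            [R, cross],
            [cross.T, np.array([[1.0, outcome_corr], [outcome_corr, 1.0]])],
        ])
    w = np.linalg.eigvalsh((R + R.T) / 2)
    if w.min() < -1e-8:
        raise InputError("factor-structured R is not positive semi-definite")
    return R


def example_four_factor_truth() -> dict:
    """Canonical 13-risk-factor, 4-factor study truth used across tests.

    Thirteen risk factors load on four correlated factors (socioeconomic,
    mood, cardiometabolic, smoking-related) with two cross-loading variables
    and one near-isolated variable (LDL, single loading 0.25, below the usual
    0.30 CFA cutoff).  The spectrum of the implied correlation matrix has
    four eigenvalues above 1 (the fifth is 0.92), so the Kaiser rule retains
    four factors with margin.  Outcome rows give the factor correlations of
    two disorders, AD and SCZ.
    """
    names = ["ALC", "LED", "SES", "SI", "MDD", "INS", "LON",
             "MAP", "T2DM", "BFP", "EYE", "SMK", "LDL"]
    L = np.zeros((13, 4))
    L[0, 0], L[1, 0], L[2, 0], L[3, 0] = 0.40, 0.85, 0.45, 0.80  # socioeconomic
    L[4, 1], L[5, 1], L[6, 1] = 0.85, 0.65, 0.75                 # mood
    L[7, 2], L[8, 2], L[9, 2], L[10, 2] = 0.70, 0.70, 0.75, 0.60  # cardiometabolic
    L[11, 3], L[0, 3], L[2, 3] = 0.90, 0.60, 0.55                # smoking-related
    L[12, 2] = 0.25                                              # LDL: below cutoff
    Phi = np.array([
        [1.00, 0.25, 0.15, 0.20],
        [0.25, 1.00, 0.10, 0.15],
        [0.15, 0.10, 1.00, 0.10],
        [0.20, 0.15, 0.10, 1.00],
    ])
    gamma = np.array([  # factor correlations of the two outcomes
        [0.19, 0.11, -0.01, 0.01],   # AD
        [0.09, 0.29, -0.09, 0.25],   # SCZ
    ])
    return {
        "risk_factors": names,
        "outcomes": ["AD", "SCZ"],
        "loadings": L,
        "factor_corr": Phi,
        "outcome_gamma": gamma,
        "outcome_corr": 0.05,
    }
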