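"""End-to-end study orchestration from a config file.

The full design mirrors a multi-trait GWAS follow-up study: munge all traits
-> multivariable LDSC (liability conversion, h2 Z > 4 power gate) ->
standardize -> per-risk-factor saturated and equality-constrained model
comparisons with FDR control -> colocalization for risk factors associated
with both outcomes -> optional region-exclusion rerun -> odd/even autosome
split with EFA on the odd and CFA on the even chromosomes -> genome-wide CFA
and factor-outcome correlations with FDR over the four factors.

FDR families follow the reporting structure: one Benjamini-Hochberg family
per outcome over the risk-factor correlations, one over the constrained-
model comparisons, and one per outcome over the factor correlations.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.stats.multitest import multipletests

from . import __version__
from .coloc import GenomicRegion, coloc_posteriors, exclude_region
from .factor import cfa_from_efa, efa, kaiser_n_factors
from .ldsc import LdScoreTable, LdscResults, multivariable_ldsc
from .sem import compare_constrained, fit_dwls, SemModel
from .sumstats import InputError, MungedTrait, ReferencePanel, munge, parse_sumstats
from . import synthgen

logger = logging.getLogger(__name__)

__all__ = ["StudyConfig", "ResultBundle", "bh_fdr", "run_study"]


def bh_fdr(p_values, alpha: float = 0.05):
    """Benjamini-Hochberg step-up: (adjusted p-values, rejection flags).

    Adjusted p_(i) = min over j >= i of m p_(j) / j, capped at 1; a test is
    rejected when its adjusted p-value is <= ``alpha``.  Empty input gives
    empty outputs.
    """
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise InputError("p-values must lie in (0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return p_adj, reject


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class StudyConfig:
    """Study definition: trait registry (or simulation block), outcome pair,
    risk factors, thresholds, optional locus list / exclusion regions."""

    outcomes: tuple[str, str]
    risk_factors: list[str]
    seed: int = 0
    n_blocks: int = 200
    min_info: float = 0.9
    min_maf: float = 0.01
    h2_z_gate: float = 4.0
    h2_z_waive: list[str] = field(default_factory=list)
    fdr_alpha: float = 0.05
    loading_cutoff: float = 0.30
    pph_threshold: float = 0.75
    simulate: dict | None = None
    data: dict | None = None
    coloc_scenarios: list[dict] = field(default_factory=list)
    coloc_always: bool = False
    exclusion_region: dict | None = None
    raw: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.outcomes) & set(self.risk_factors):
            raise InputError("outcomes must be distinct from risk factors")
        for name, v in (("min_info", self.min_info), ("min_maf", self.min_maf),
                        ("fdr_alpha", self.fdr_alpha),
                        ("loading_cutoff", self.loading_cutoff),
                        ("pph_threshold", self.pph_threshold)):
            if not (0 <= v <= 1):
                raise InputError(f"threshold {name} out of range: {v}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "StudyConfig":
        thr = doc.get("thresholds", {})
        return cls(
            outcomes=tuple(doc["outcomes"]),
            risk_factors=list(doc["risk_factors"]),
            seed=int(doc.get("seed", 0)),
            n_blocks=int(doc.get("n_blocks", 200)),
            min_info=thr.get("min_info", 0.9),
            min_maf=thr.get("min_maf", 0.01),
            h2_z_gate=thr.get("h2_z_gate", 4.0),
            h2_z_waive=list(doc.get("h2_z_waive", [])),
            fdr_alpha=thr.get("fdr_alpha", 0.05),
            loading_cutoff=thr.get("loading_cutoff", 0.30),
            pph_threshold=thr.get("pph_threshold", 0.75),
            simulate=doc.get("simulate"),
            data=doc.get("data"),
            coloc_scenarios=list(doc.get("coloc_scenarios", [])),
            coloc_always=bool(doc.get("coloc_always", False)),
            exclusion_region=doc.get("exclusion_region"),
            raw=doc,
        )

    def config_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------

@dataclass
class ResultBundle:
    """Machine-readable study output with provenance."""

    ldsc: dict
    rg_table: list[dict]
    coloc_table: list[dict]
    exclusion: dict | None
    efa: dict | None
    cfa: dict | None
    factor_outcome: list[dict]
    provenance: dict
    log: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "ldsc": self.ldsc, "rg_table": self.rg_table,
            "coloc_table": self.coloc_table, "exclusion": self.exclusion,
            "efa": self.efa, "cfa": self.cfa,
            "factor_outcome": self.factor_outcome,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=2)

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(self.to_json())
        if self.rg_table:
            pd.DataFrame(self.rg_table).to_csv(out / "rg_table.tsv", sep="\t", index=False)
        if self.coloc_table:
            pd.DataFrame(self.coloc_table).to_csv(out / "coloc_table.tsv", sep="\t", index=False)
        if self.factor_outcome:
            pd.DataFrame(self.factor_outcome).to_csv(
                out / "factor_outcome.tsv", sep="\t", index=False)
        (out / "log.json").write_text(json.dumps(self.log, indent=2))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _load_or_simulate(config: StudyConfig):
    """Return (traits in config order, LdScoreTable, ReferencePanel)."""
    order = list(config.risk_factors) + list(config.outcomes)
    if config.simulate is not None:
        sim = config.simulate
        M = int(sim.get("M", 20_000))
        ld = synthgen.simulate_ld_scores(
            M, mean=sim.get("ld_mean", 100.0), shape=sim.get("ld_shape", 3.0),
            seed=config.seed)
        specs = [synthgen.TraitSpec(**t) for t in sim["traits"]]
        if "factor_structure" in sim:
            fs = sim["factor_structure"]
            R = synthgen.factor_structure_R(
                np.asarray(fs["loadings"], dtype=float),
                np.asarray(fs["factor_corr"], dtype=float),
                np.asarray(fs["outcome_gamma"], dtype=float) if "outcome_gamma" in fs else None,
                fs.get("outcome_corr", 0.0),
            )
        else:
            R = np.asarray(sim["R_true"], dtype=float)
        truth = synthgen.SyntheticTruth(
            traits=specs, R_true=R, M=M, seed=config.seed,
            overlap=np.asarray(sim["overlap"]) if sim.get("overlap") is not None else None,
            pheno_corr=np.asarray(sim["pheno_corr"]) if sim.get("pheno_corr") is not None else None,
        )
        traits = {t.trait_name: t for t in synthgen.simulate_sumstats(truth, ld)}
        panel = synthgen.make_panel(ld, seed=config.seed)
    else:
        data = config.data or {}
        panel = ReferencePanel.from_file(data["panel"])
        ld = LdScoreTable.from_files(data["ld_scores"], data["ld_m"])
        traits = {}
        for spec in data["traits"]:
            raw = parse_sumstats(spec["path"], spec["column_map"],
                                 trait_name=spec["name"],
                                 n_default=spec.get("n_default"))
            traits[spec["name"]] = munge(
                raw, panel, min_info=config.min_info, min_maf=config.min_maf,
                binary=spec.get("binary", False),
                sample_prev=spec.get("P"), pop_prev=spec.get("K"))
    missing = [n for n in order if n not in traits]
    if missing:
        raise InputError(f"configured traits not found in inputs: {missing}")
    return [traits[n] for n in order], ld, panel


def _ldsc_stage(traits: list[MungedTrait], ld: LdScoreTable,
                config: StudyConfig, gate: bool = True) -> LdscResults:
    """LDSC + liability conversion; the h2 Z power screen applies only to the
    genome-wide run (gate=True), not to chromosome-subset reruns."""
    res = multivariable_ldsc(traits, ld, n_blocks=config.n_blocks)
    prevalences = {
        t.trait_name: (t.pop_prev, t.sample_prev)
        for t in traits
        if t.binary and t.pop_prev is not None and t.sample_prev is not None
    }
    if prevalences:
        res = res.to_liability(prevalences)
    if not gate:
        return res
    failing = [
        (t, float(z)) for t, z in zip(res.traits, res.h2_z)
        if z <= config.h2_z_gate and t not in config.h2_z_waive
    ]
    if failing:
        raise InputError(
            "traits fail the heritability Z gate "
            f"(h2_z <= {config.h2_z_gate}): {failing}"
        )
    return res


def _risk_factor_stage(corr, config: StudyConfig) -> list[dict]:
    o1, o2 = config.outcomes
    rows = []
    for rf in config.risk_factors:
        cc = compare_constrained(corr, (o1, o2), rf)
        rows.append({
            "risk_factor": rf,
            f"rg_{o1}": cc.rg_1, f"se_{o1}": cc.se_1,
            f"p_{o1}": 2 * stats.norm.sf(abs(cc.rg_1 / cc.se_1)) if cc.se_1 > 0 else 1.0,
            f"rg_{o2}": cc.rg_2, f"se_{o2}": cc.se_2,
            f"p_{o2}": 2 * stats.norm.sf(abs(cc.rg_2 / cc.se_2)) if cc.se_2 > 0 else 1.0,
            "chi2_diff": cc.chi2_diff, "p_diff": cc.p_diff,
        })
    for fam in (f"p_{o1}", f"p_{o2}", "p_diff"):
        adj, rej = bh_fdr([r[fam] for r in rows], config.fdr_alpha)
        for r, a, j in zip(rows, adj, rej):
            r[f"{fam}_fdr"] = float(a)
            r[f"{fam}_sig"] = bool(j)
    return rows


def _coloc_stage(config: StudyConfig, rg_rows: list[dict]) -> list[dict]:
    o1, o2 = config.outcomes
    triggered = config.coloc_always or any(
        r[f"p_{o1}_sig"] and r[f"p_{o2}_sig"] for r in rg_rows
    )
    if not triggered or not config.coloc_scenarios:
        return []
    out = []
    for i, sc in enumerate(config.coloc_scenarios):
        locus = synthgen.simulate_coloc_locus(
            sc["hypothesis"], n_snps=int(sc.get("n_snps", 200)),
            ld_rho=sc.get("ld_rho", 0.9), causal_z=sc.get("causal_z", 8.0),
            seed=config.seed + i,
        )
        res = coloc_posteriors(locus, pph_threshold=config.pph_threshold)
        out.append({
            "locus_id": res.locus_id, "n_snps": res.n_snps,
            "pph0": res.pph0, "pph1": res.pph1, "pph2": res.pph2,
            "pph3": res.pph3, "pph4": res.pph4, "call": res.call,
        })
    return out


def _exclusion_stage(config: StudyConfig, traits, ld, panel, corr) -> dict | None:
    if config.exclusion_region is None:
        return None
    reg = GenomicRegion(**config.exclusion_region)
    filt = exclude_region(traits, reg, panel)
    res2 = _ldsc_stage(filt, ld, config, gate=False)
    corr2 = res2.standardize()
    rows = _risk_factor_stage(corr2, config)
    return {
        "region": {"chromosome": reg.chromosome, "start": reg.start, "end": reg.end},
        "rg_table": rows,
    }


def _factor_stage(config: StudyConfig, traits, ld, corr_all):
    """Odd-autosome EFA, even-autosome CFA, genome-wide CFA + factor-outcome."""
    o1, o2 = config.outcomes
    rf_names = list(config.risk_factors)

    def chrom_subset(parity: int) -> LdScoreTable:
        tab = ld.table[ld.table["CHR"] % 2 == parity]
        return LdScoreTable(tab.reset_index(drop=True), m_total=float(len(tab)))

    rf_traits = [t for t in traits if t.trait_name in rf_names]
    corr_odd = _ldsc_stage(rf_traits, chrom_subset(1), config, gate=False).standardize()
    n_factors = kaiser_n_factors(corr_odd.R)
    if n_factors < 1:
        return {"n_factors": 0}, None, []
    efa_res = efa(corr_odd.R, n_factors, variables=corr_odd.traits)
    model, excluded = cfa_from_efa(efa_res, cutoff=config.loading_cutoff)

    corr_even = _ldsc_stage(rf_traits, chrom_subset(0), config, gate=False).standardize()
    cfa_even = fit_dwls(model, corr_even)

    corr_rf_all = corr_all.subset(rf_names)
    cfa_all = fit_dwls(model, corr_rf_all)

    efa_block = {
        "n_factors": n_factors,
        "variance_explained": efa_res.variance_explained,
        "loadings": {v: {f: float(efa_res.loadings.loc[v, f])
                         for f in efa_res.factors}
                     for v in efa_res.variables},
        "factor_correlations": efa_res.factor_correlations.tolist(),
        "excluded": excluded,
        "smoothing_distance": efa_res.smoothing_distance,
    }
    cfa_block = {
        "model": model.to_text(),
        "even_autosomes": {k: getattr(cfa_even, k) for k in
                           ("chi2", "df", "aic", "cfi", "srmr")},
        "all_autosomes": {k: getattr(cfa_all, k) for k in
                          ("chi2", "df", "aic", "cfi", "srmr")},
        "heywood": cfa_all.heywood,
    }

    # factor-outcome correlations on the genome-wide matrix
    factors = [f for f in model.latents]
    ext_lines = [model.to_text()]
    for o in (o1, o2):
        for f in factors:
            ext_lines.append(f"{o} ~~ {f}")
    ext_lines.append(f"{o1} ~~ {o2}")
    free_model = SemModel.from_text("\n".join(ext_lines))
    corr_ext = corr_all.subset([t for t in corr_all.traits
                                if t in free_model.observed])
    free_fit = fit_dwls(free_model, corr_ext)

    rows = []
    for f in factors:
        row = {"factor": f}
        for o in (o1, o2):
            est, se = free_fit.estimate(f"{o}~~{f}")
            row[f"rg_{o}"] = est
            row[f"se_{o}"] = se
            row[f"p_{o}"] = 2 * stats.norm.sf(abs(est / se)) if se > 0 else 1.0
        con_lines = [model.to_text()]
        for ff in factors:
            if ff == f:
                con_lines.append(f"{o1} ~~ eqc*{ff}")
                con_lines.append(f"{o2} ~~ eqc*{ff}")
            else:
                con_lines.append(f"{o1} ~~ {ff}")
                con_lines.append(f"{o2} ~~ {ff}")
        con_lines.append(f"{o1} ~~ {o2}")
        con_fit = fit_dwls(SemModel.from_text("\n".join(con_lines)), corr_ext)
        chi2_diff = max(con_fit.chi2 - free_fit.chi2, 0.0)
        row["chi2_diff"] = chi2_diff
        row["p_diff"] = float(stats.chi2.sf(chi2_diff, 1))
        rows.append(row)
    for fam in (f"p_{o1}", f"p_{o2}", "p_diff"):
        adj, rej = bh_fdr([r[fam] for r in rows], config.fdr_alpha)
        for r, a, j in zip(rows, adj, rej):
            r[f"{fam}_fdr"] = float(a)
            r[f"{fam}_sig"] = bool(j)
    return efa_block, cfa_block, rows


def run_study(config: StudyConfig) -> ResultBundle:
    """Execute the full study design and return a deterministic bundle."""
    log: list[dict] = []

    def stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            log.append({"stage": name, "seconds": round(time.perf_counter() - t0, 3),
                        **counts})
        return done

    d = stage("load")
    traits, ld, panel = _load_or_simulate(config)
    d(n_traits=len(traits), n_snps=int(len(ld.table)))

    d = stage("ldsc")
    res = _ldsc_stage(traits, ld, config)
    corr = res.standardize()
    d(k=res.k)

    ldsc_block = {
        "traits": res.traits,
        "h2": {t: {"est": float(res.S[i, i]), "z": float(res.h2_z[i]),
                   "intercept": float(res.intercepts[i, i])}
               for i, t in enumerate(res.traits)},
        "R": corr.R.tolist(),
    }

    d = stage("risk_factors")
    rg_rows = _risk_factor_stage(corr, config)
    d(n=len(rg_rows))

    d = stage("coloc")
    coloc_rows = _coloc_stage(config, rg_rows)
    d(n=len(coloc_rows))

    d = stage("exclusion")
    excl = _exclusion_stage(config, traits, ld, panel, corr)
    d(ran=excl is not None)

    d = stage("factor_analysis")
    efa_block, cfa_block, fo_rows = _factor_stage(config, traits, ld, corr)
    d(n_factors=efa_block.get("n_factors") if efa_block else 0)

    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "gsemkit_version": __version__,
    }
    return ResultBundle(
        ldsc=ldsc_block, rg_table=rg_rows, coloc_table=coloc_rows,
        exclusion=excl, efa=efa_block, cfa=cfa_block,
        factor_outcome=fo_rows, provenance=provenance, log=log,
    )
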