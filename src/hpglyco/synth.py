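"""Synthetic glycopeptide cohorts with known ground truth.

No clinical glycoproteomics cohort of this design is publicly deposited, so
the pipeline is exercised on generated data that mirror the study structure:

* three clinical groups (liver-disease controls, early- and late-stage HCC,
  defaults 57/50/32 samples);
* four haptoglobin glycosites carrying 36/42/31/50 glycoforms (N184, N207,
  N211, N241), drawn from a realistic composition catalog so the glycan
  classifier produces fucosylated, sialylated, branched and high-mannose
  classes;
* baseline abundances spanning ~5 decades (log10-uniform), matching the
  observed XIC dynamic range;
* multiplicative disease effects on selected feature classes, parameterized
  as *designed AUCs* via the binormal identity AUC = Phi(delta / (sigma
  sqrt(2))) on the log scale, monotone from early to late disease;
* a per-sample technical factor applied to every glycopeptide row and to the
  heavy internal-standard table (so top-3 normalization can remove it), plus
  log-normal technical noise at ~10% CV;
* hard left-censoring of low-abundance values (set missing), emulating
  glycoforms that fall below the identification limit;
* Hp phenotype labels (1-1 / 2-1 / 2-2 / unknown) and etiology/cirrhosis
  flags at the study's observed proportions.

Every generated row is covered by a ground-truth ledger (baseline,
fold-changes, designed AUCs, marker flags) enabling parameter-recovery
tests.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .glyco import GlycanComposition, classify, format_composition
from .quant import ROW_ID_SEP, make_row_id

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticCohort",
    "site_catalog",
    "generate_cohort",
    "inject_phenotype_structure",
    "write_cohort",
]

#: Feature classes the effect map may address (as produced by aggregation).
EFFECT_CLASSES = (
    "fucosylation", "sialylation", "branching", "high-mannose",
)

# Hp phenotype proportions per group, from the study cohort table
# (remainder = phenotype not identified).
DEFAULT_PHENOTYPE_PROPS: Mapping[str, Mapping[str, float]] = {
    "control": {"1-1": 0.053, "2-1": 0.58, "2-2": 0.35},
    "early": {"1-1": 0.08, "2-1": 0.32, "2-2": 0.52},
    "late": {"1-1": 0.063, "2-1": 0.47, "2-2": 0.38},
}

# Disease effects, expressed as designed AUCs vs the control group.
# Fucosylated, branched (tri/tetra-antennary) and high-mannose glycoforms go
# up in early HCC and further up in late HCC; highly sialylated forms follow.
DEFAULT_EFFECT_MAP: Mapping[str, Mapping[str, float]] = {
    "fucosylation": {"early": 0.75, "late": 0.85},
    "branching": {"early": 0.72, "late": 0.82},
    "high-mannose": {"early": 0.70, "late": 0.80},
    "sialylation": {"early": 0.65, "late": 0.75},
}


@dataclass(frozen=True)
class GeneratorConfig:
    n_control: int = 57
    n_early: int = 50
    n_late: int = 32
    site_glycoforms: Mapping[str, int] = field(
        default_factory=lambda: {"N184": 36, "N207": 42, "N211": 31, "N241": 50}
    )
    decades: float = 5.0  # baseline log10 dynamic range
    base_log10: float = 3.0  # lowest baseline decade
    bio_sd_log10: float = 0.30  # between-subject biological sd, log10 units
    technical_cv: float = 0.10  # per-measurement multiplicative noise
    sample_factor_cv: float = 0.25  # per-sample handling/injection factor
    effect_map: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_EFFECT_MAP
    )
    effect_fraction: float = 0.5  # fraction of rows in a class that carry the effect
    censor_quantile: float = 0.05  # left-censoring threshold quantile (0 disables)
    n_heavy_peptides: int = 6
    phenotype_props: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: DEFAULT_PHENOTYPE_PROPS
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_control, self.n_early, self.n_late) < 2:
            raise ValueError("each group needs >= 2 samples")
        if self.decades <= 0:
            raise ValueError("decades must be > 0")
        if self.technical_cv < 0 or self.sample_factor_cv < 0:
            raise ValueError("CVs must be >= 0")
        if not 0 <= self.censor_quantile < 1:
            raise ValueError("censor_quantile must be in [0, 1)")
        for cls in self.effect_map:
            if cls not in EFFECT_CLASSES:
                raise ValueError(
                    f"unknown feature class {cls!r} in effect map; "
                    f"allowed: {EFFECT_CLASSES}"
                )
        for grp, props in self.phenotype_props.items():
            if sum(props.values()) > 1 + 1e-9:
                raise ValueError(f"phenotype proportions for {grp!r} sum > 1")


@dataclass
class SyntheticTruth:
    """Ground-truth ledger: designed effects per row, factors per sample."""

    rows: pd.DataFrame  # baseline_log10, fc_early, fc_late, auc_early, auc_late, is_marker, effect_class
    sample_factors: pd.Series  # per-sample technical factor
    sigma_log10: float  # total within-group sd used for the binormal identity


@dataclass
class SyntheticCohort:
    matrix: pd.DataFrame
    heavy: pd.DataFrame
    meta: pd.DataFrame
    truth: SyntheticTruth


def site_catalog(n_forms: int, rng: np.random.Generator) -> list[GlycanComposition]:
    """Draw `n_forms` distinct, realistic compositions for one glycosite.

    The pool holds the common complex series (bi/tri/tetra-antennary with
    0..antennae sialic acids and 0..3 fucoses, with and without a bisecting
    HexNAc), the Man5-Man9 high-mannose series and a few hybrids — ordered so
    that abundant canonical forms (sialylated biantennary first) are always
    present, as observed for haptoglobin.
    """
    pool: list[GlycanComposition] = []
    # canonical complex forms, most prevalent first
    for hexnac in (4, 5, 6):
        ant = hexnac - 2
        hx = ant + 3  # fully galactosylated
        for neuac in range(0, ant + 1):
            for fuc in range(0, 4):
                pool.append(GlycanComposition(hexnac, hx, fuc, neuac))
    # bisected variants (extra HexNAc without galactose)
    for hexnac in (5, 6):
        hx = hexnac + 0  # hexnac-2 > hex-3  <=>  hex < hexnac + 1
        for neuac in range(0, hexnac - 2):
            for fuc in (0, 1):
                pool.append(GlycanComposition(hexnac, hx, fuc, neuac))
    # high-mannose Man5..Man9
    pool += [GlycanComposition(2, hx) for hx in range(5, 10)]
    # hybrids
    pool += [GlycanComposition(3, hx, fuc, neuac)
             for hx, fuc, neuac in itertools.product((5, 6), (0, 1), (0, 1))]
    seen = set()
    uniq = [c for c in pool if not (c in seen or seen.add(c))]
    if n_forms > len(uniq):
        raise ValueError(f"catalog pool ({len(uniq)}) smaller than requested {n_forms}")
    head = uniq[: min(8, n_forms)]  # canonical abundant forms always included
    tail = list(rng.permutation(len(uniq) - len(head)) + len(head))[: n_forms - len(head)]
    return head + [uniq[i] for i in tail]


def _row_effect_class(comp: GlycanComposition) -> str | None:
    """Feature class through which the effect map addresses a composition."""
    cls = classify(comp)
    if cls.family == "high-mannose":
        return "high-mannose"
    if cls.family == "complex":
        if cls.fucosylation_degree >= 1:
            return "fucosylation"
        if cls.antennae >= 3:
            return "branching"
        if cls.sialylation_degree >= 2:
            return "sialylation"
    return None


def _auc_to_delta(auc: float, sigma: float) -> float:
    """Binormal identity: a mean shift delta on a normal scale with
    within-group sd sigma yields AUC = Phi(delta / (sigma sqrt(2)))."""
    return float(norm.ppf(auc) * sigma * np.sqrt(2.0))


def generate_cohort(config: GeneratorConfig | None = None) -> SyntheticCohort:
    """Generate a full cohort: quant matrix, heavy table, metadata, truth."""
    cfg = config or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed)

    groups = (["control"] * cfg.n_control + ["early"] * cfg.n_early
              + ["late"] * cfg.n_late)
    samples = [f"S{i + 1:03d}" for i in range(len(groups))]
    meta = pd.DataFrame({"group": groups}, index=pd.Index(samples, name="sample"))
    meta = inject_phenotype_structure(meta, cfg, rng)

    # catalog and per-row designed effects
    row_ids, comps = [], []
    for site, n_forms in cfg.site_glycoforms.items():
        for comp in site_catalog(n_forms, rng):
            row_ids.append(make_row_id(site, format_composition(comp)))
            comps.append(comp)

    tech_sd_log10 = np.sqrt(np.log(1 + cfg.technical_cv**2)) / np.log(10)
    sigma = float(np.hypot(cfg.bio_sd_log10, tech_sd_log10))

    baseline = rng.uniform(cfg.base_log10, cfg.base_log10 + cfg.decades, len(row_ids))
    truth_rows = []
    delta_early = np.zeros(len(row_ids))
    delta_late = np.zeros(len(row_ids))
    for i, comp in enumerate(comps):
        ecls = _row_effect_class(comp)
        is_marker = False
        de = dl = 0.0
        if ecls is not None and ecls in cfg.effect_map:
            # only a fraction of each class carries the designed effect
            if rng.random() < cfg.effect_fraction:
                is_marker = True
                de = _auc_to_delta(cfg.effect_map[ecls].get("early", 0.5), sigma)
                dl = _auc_to_delta(cfg.effect_map[ecls].get("late", 0.5), sigma)
        delta_early[i], delta_late[i] = de, dl
        truth_rows.append(
            dict(row=row_ids[i], baseline_log10=baseline[i],
                 fc_early=10.0**de, fc_late=10.0**dl,
                 auc_early=float(norm.cdf(de / (sigma * np.sqrt(2)))),
                 auc_late=float(norm.cdf(dl / (sigma * np.sqrt(2)))),
                 is_marker=is_marker, effect_class=ecls or "")
        )

    shift = np.zeros((len(row_ids), len(samples)))
    grp_arr = np.asarray(groups)
    shift[:, grp_arr == "early"] = delta_early[:, None]
    shift[:, grp_arr == "late"] = delta_late[:, None]

    bio = rng.normal(0.0, cfg.bio_sd_log10, size=shift.shape)
    tech = rng.normal(0.0, tech_sd_log10, size=shift.shape)
    sample_factor = rng.lognormal(0.0, np.sqrt(np.log(1 + cfg.sample_factor_cv**2)),
                                  size=len(samples))
    log10_vals = baseline[:, None] + shift + bio + tech
    values = 10.0**log10_vals * sample_factor[None, :]

    matrix = pd.DataFrame(values, index=pd.Index(row_ids, name="glyco-compound"),
                          columns=samples)

    # left-censor: values below the global abundance quantile go missing
    if cfg.censor_quantile > 0:
        threshold = float(np.quantile(values, cfg.censor_quantile))
        matrix = matrix.mask(matrix < threshold)

    # heavy internal standard: fixed peptide levels x sample factor x noise
    heavy_base = 10.0 ** rng.uniform(5.0, 6.5, cfg.n_heavy_peptides)
    heavy_noise = rng.lognormal(0.0, np.sqrt(np.log(1 + cfg.technical_cv**2)),
                                size=(cfg.n_heavy_peptides, len(samples)))
    heavy = pd.DataFrame(
        heavy_base[:, None] * sample_factor[None, :] * heavy_noise,
        index=pd.Index([f"HPEP{i + 1:02d}" for i in range(cfg.n_heavy_peptides)],
                       name="heavy-peptide"),
        columns=samples,
    )

    truth = SyntheticTruth(
        rows=pd.DataFrame(truth_rows).set_index("row"),
        sample_factors=pd.Series(sample_factor, index=samples, name="factor"),
        sigma_log10=sigma,
    )
    return SyntheticCohort(matrix, heavy, meta, truth)


def inject_phenotype_structure(
    meta: pd.DataFrame,
    config: GeneratorConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Assign Hp phenotypes, etiology flags and cirrhosis status.

    Phenotype counts follow the configured per-group proportions
    deterministically (count = round(n x p), remainder 'unknown'); which
    sample gets which label is randomized. Etiology and cirrhosis flags are
    drawn at rates resembling a mixed viral-etiology HCC cohort.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    meta = meta.copy()
    phen = pd.Series("unknown", index=meta.index, dtype=object)
    for grp, props in config.phenotype_props.items():
        ids = meta.index[meta["group"] == grp]
        n = len(ids)
        counts = {ph: int(round(n * p)) for ph, p in props.items()}
        if sum(counts.values()) > n:
            raise ValueError(f"phenotype counts exceed group size for {grp!r}")
        order = rng.permutation(n)
        pos = 0
        for ph, cnt in counts.items():
            phen.loc[ids[order[pos : pos + cnt]]] = ph
            pos += cnt
    meta["phenotype"] = phen
    n = len(meta)
    is_hcc = meta["group"].isin(["early", "late"]).to_numpy()
    hbv = rng.random(n) < np.where(is_hcc, 0.40, 0.30)
    hcv = (~hbv) & (rng.random(n) < np.where(is_hcc, 0.35, 0.30))
    ash = (~hbv) & (~hcv) & (rng.random(n) < 0.25)
    nash = (~hbv) & (~hcv) & (~ash)
    meta["HBV"] = np.where(hbv, "yes", "no")
    meta["HCV"] = np.where(hcv, "yes", "no")
    meta["ASH"] = np.where(ash, "yes", "no")
    meta["NASH"] = np.where(nash, "yes", "no")
    meta["cirrhosis"] = np.where(rng.random(n) < np.where(is_hcc, 0.80, 0.85),
                                 "yes", "no")
    # AFP benchmark: log-normal with a designed AUC of 0.79 for HCC vs control
    afp_sd = 0.5  # log10 ng/ml within-group sd
    afp_delta = _auc_to_delta(0.79, afp_sd)
    log10_afp = 1.0 + rng.normal(0.0, afp_sd, n) + np.where(is_hcc, afp_delta, 0.0)
    meta["AFP"] = np.round(10.0**log10_afp, 2)
    return meta


def write_cohort(cohort: SyntheticCohort, outdir) -> dict[str, str]:
    """Write the cohort in the tabular formats the quant module reads."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "quant": outdir / "quant_matrix.tsv",
        "heavy": outdir / "heavy_standard.tsv",
        "meta": outdir / "sample_meta.tsv",
        "truth": outdir / "truth_ledger.tsv",
        "factors": outdir / "truth_sample_factors.tsv",
    }
    cohort.matrix.to_csv(paths["quant"], sep="\t", na_rep="")
    cohort.heavy.to_csv(paths["heavy"], sep="\t")
    cohort.meta.to_csv(paths["meta"], sep="\t")
    cohort.truth.rows.to_csv(paths["truth"], sep="\t")
    cohort.truth.sample_factors.to_csv(paths["factors"], sep="\t")
    return {k: str(v) for k, v in paths.items()}
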