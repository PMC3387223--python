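"""Synthetic Infinium-27K-style methylation study generator.

Emulates a two-arm early-stage NSCLC cohort profiled on a promoter-centric
27K methylation array together with a matched expression array and clinical
follow-up, with planted ground truth for every downstream screen:

* a probe manifest of promoter CpGs (1–3 per gene) within −1.5 kb .. +1 kb of
  the TSS, island membership decaying with distance from the TSS;
* bimodal beta baselines (island probes low, non-island high) with
  Beta-distributed array noise so values stay in [0, 1];
* planted tumor-vs-normal hyper-/hypomethylation with island/TSS-proximal
  (hyper) vs shore/upstream (hypo) positional enrichment, plus an analogous
  SCC-vs-AC layer inside the tumor arm;
* inverse methylation→expression coupling for a configurable fraction of the
  differentially methylated genes;
* survival times with hazards driven by the discretized methylation of
  planted prognostic CpGs, administratively censored;
* technical replicate pairs, smoking covariates (pack-years + smoker flag,
  one patient with missing smoking data), two early post-operative deaths,
  and optionally low-purity "diluted" tumors.

Everything is deterministic given ``SimulationConfig.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .dataio import (
    ExpressionMatrix,
    ValidationError,
    write_beta,
    write_expression,
    write_manifest,
    write_sample_sheet,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "generate_manifest",
    "call_cpg_islands",
    "simulate_dataset",
    "write_dataset",
]


@dataclass
class SimulationConfig:
    """Study-design and effect-structure knobs for the simulator.

    Defaults mirror the emulated cohort: 48 stage-I tumors (32 SCC + 16 AC)
    vs 18 cancer-free lung controls, 2 technical replicate pairs, 3
    non-smokers, and an array scaled to 1000 promoter CpGs in 600 genes.
    """

    n_probes: int = 1000
    n_genes: int = 600
    n_tumor: int = 48
    n_normal: int = 18
    n_scc: int = 32
    n_ac: int = 16
    frac_hyper: float = 0.05
    frac_hypo: float = 0.04
    delta_effect: float = 0.2
    beta_precision: float = 50.0
    island_fraction: float = 0.7
    enrichment_odds: float = 8.0
    frac_expr_coupled: float = 0.435
    coupling_slope: float = 2.5
    n_prognostic_cpgs: int = 1
    hazard_log_ratio: float = 1.0
    baseline_hazard: float = 0.008
    censor_horizon: float = 120.0
    n_replicate_pairs: int = 2
    n_nonsmokers: int = 3
    seed: int = 0
    # secondary layers beyond the core field set
    frac_scc_hyper: float = 0.01
    frac_scc_hypo: float = 0.02
    n_smoker_cpgs: int = 4
    smoker_delta: float = -0.15
    n_packyear_cpgs: int = 0
    packyear_slope: float = 0.0
    frac_variable: float = 0.2
    n_diluted: int = 0
    dilution_purity: float = 0.2
    replicate_noise_sd: float = 0.01

    def validate(self) -> "SimulationConfig":
        for name in (
            "frac_hyper", "frac_hypo", "island_fraction", "frac_expr_coupled",
            "frac_scc_hyper", "frac_scc_hypo", "frac_variable", "dilution_purity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}", code="config")
        if self.frac_hyper + self.frac_hypo > 1:
            raise ValidationError("frac_hyper + frac_hypo must be <= 1", code="config")
        for name in ("n_probes", "n_genes", "n_tumor", "n_normal"):
            if getattr(self, name) < 1:
                raise ValidationError(f"{name} must be positive", code="config")
        for name in (
            "n_scc", "n_ac", "n_prognostic_cpgs", "n_replicate_pairs",
            "n_nonsmokers", "n_smoker_cpgs", "n_packyear_cpgs", "n_diluted",
        ):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative", code="config")
        if self.n_scc + self.n_ac != self.n_tumor:
            raise ValidationError("n_scc + n_ac must equal n_tumor", code="config")
        if self.n_probes < self.n_genes:
            raise ValidationError("n_probes must be >= n_genes", code="config")
        for name in ("delta_effect",):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1]", code="config")
        for name in ("beta_precision", "enrichment_odds", "baseline_hazard",
                     "censor_horizon"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive", code="config")
        return self

    def replace(self, **kw) -> "SimulationConfig":
        d = asdict(self)
        d.update(kw)
        return SimulationConfig(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config fields {sorted(unknown)}", code="config")
        return cls(**raw).validate()


@dataclass
class GroundTruth:
    """Planted structure: per-probe effect table and per-sample hazard table.

    ``probes`` columns: direction ('hyper'/'hypo'/'none'), true_delta,
    scc_direction, expr_coupled, prognostic, smoker_effect, packyear_slope.
    ``samples`` columns: group (tumor/normal), hazard_multiplier, diluted.
    """

    probes: pd.DataFrame
    samples: pd.DataFrame

    def planted(self, direction: str | None = None) -> pd.Index:
        mask = self.probes["direction"] != "none"
        if direction is not None:
            mask = self.probes["direction"] == direction
        return self.probes.index[mask]


@dataclass
class SimulatedDataset:
    beta: pd.DataFrame
    expression: ExpressionMatrix
    sheet: pd.DataFrame
    manifest: pd.DataFrame
    truth: GroundTruth
    config: SimulationConfig = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# manifest


def generate_manifest(config: SimulationConfig) -> pd.DataFrame:
    """Draw a promoter-probe manifest: genes with 1–3 CpGs each, signed TSS
    distances on [−1500, +1000] bp, island membership decaying with |distance|.
    """
    config.validate()
    rng = np.random.default_rng(_stream(config.seed, 1))
    n, g = config.n_probes, config.n_genes

    # give every gene one probe, distribute the surplus as 2nd/3rd probes
    gene_of = np.arange(g)
    surplus = n - g
    if surplus > 0:
        capacity = np.repeat(np.arange(g), 2)  # room for two extra probes/gene
        if surplus > len(capacity):
            raise ValidationError(
                "n_probes exceeds 3 probes per gene; raise n_genes", code="config"
            )
        extra = rng.choice(capacity, size=surplus, replace=False)
        gene_of = np.concatenate([gene_of, extra])
    rng.shuffle(gene_of)

    dist = rng.integers(-1500, 1001, size=n)
    # island probability decays with distance from the TSS; scaled so the
    # overall island rate matches island_fraction
    decay = np.exp(-np.abs(dist) / 700.0)
    p_island = np.clip(decay * config.island_fraction / decay.mean(), 0, 1)
    island = rng.random(n) < p_island

    width = len(str(n))
    manifest = pd.DataFrame(
        {
            "gene": [f"G{j:0{len(str(g))}d}" for j in gene_of],
            "dist_tss": dist,
            "island": island,
        },
        index=pd.Index([f"cg{i:0{width}d}" for i in range(n)], name="cpg_id"),
    )
    return manifest


# ---------------------------------------------------------------------------
# CpG island caller


def call_cpg_islands(
    sequence: str,
    min_len: int = 200,
    min_gc: float = 0.5,
    min_oe: float = 0.6,
) -> list[tuple[int, int]]:
    """Call CpG islands: maximal merged unions of all windows that are
    >= *min_len* bp, have GC fraction >= *min_gc* and observed/expected CpG
    ratio >= *min_oe*, where obs/exp = (#CG dinucleotides x window length) /
    (#C x #G). Intervals are 0-based half-open. Windows with #C x #G = 0 fail.

    O(L^2) over window (start, length) pairs via prefix sums — fine for the
    promoter-scale sequences this package handles.
    """
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in "ACGT":
            raise ValidationError(
                f"non-ACGT character {ch!r} at position {pos}", code="sequence"
            )
    L = len(seq)
    if L < min_len:
        return []
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    cum_c = np.concatenate([[0], np.cumsum(is_c)])
    cum_g = np.concatenate([[0], np.cumsum(is_g)])
    is_cg = np.zeros(L, dtype=np.int64)
    if L > 1:
        is_cg[:-1] = is_c[:-1] & is_g[1:]
    cum_cg = np.concatenate([[0], np.cumsum(is_cg)])

    covered = np.zeros(L, dtype=bool)
    for w in range(min_len, L + 1):
        starts = np.arange(L - w + 1)
        ends = starts + w
        c = cum_c[ends] - cum_c[starts]
        g = cum_g[ends] - cum_g[starts]
        cg = cum_cg[ends - 1] - cum_cg[starts]  # CG fully inside the window
        gc_ok = (c + g) >= min_gc * w
        denom = c * g
        oe_ok = np.zeros_like(gc_ok)
        nz = denom > 0
        oe_ok[nz] = cg[nz] * w >= min_oe * denom[nz]
        passing = np.flatnonzero(gc_ok & oe_ok)
        for s in passing:
            covered[s : s + w] = True

    return _runs(covered)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    edges = np.flatnonzero(np.diff(np.concatenate([[0], mask.view(np.int8), [0]])))
    return [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]


# ---------------------------------------------------------------------------
# full dataset


def _stream(seed: int, k: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=int(seed), spawn_key=(k,))


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Simulate the full study: beta matrix, expression, sample sheet, truth."""
    config.validate()
    manifest = generate_manifest(config)
    rng = np.random.default_rng(_stream(config.seed, 2))
    n = config.n_probes
    nt, nn = config.n_tumor, config.n_normal
    n_samples = nt + nn

    sample_ids = [f"T{i + 1:02d}" for i in range(nt)] + [
        f"N{i + 1:02d}" for i in range(nn)
    ]
    tumor = np.arange(n_samples) < nt
    histology = np.array(
        ["SCC"] * config.n_scc + ["AC"] * config.n_ac + [None] * nn, dtype=object
    )

    island = manifest["island"].to_numpy()
    dist = manifest["dist_tss"].to_numpy()

    # --- baseline means: bimodal (island low, non-island high) ---
    mu0 = np.where(
        island,
        rng.beta(2.0, 12.0, size=n),  # islands mostly unmethylated
        rng.beta(12.0, 3.0, size=n),  # open sea mostly methylated
    )
    mu0 = np.clip(mu0, 0.02, 0.98)

    # --- planted differential layers ---
    truth_probes = pd.DataFrame(
        {
            "direction": "none",
            "true_delta": 0.0,
            "scc_direction": "none",
            "expr_coupled": False,
            "prognostic": False,
            "smoker_effect": False,
            "packyear_slope": 0.0,
        },
        index=manifest.index,
    )

    n_hyper = int(round(config.frac_hyper * n))
    n_hypo = int(round(config.frac_hypo * n))
    hyper_idx, hypo_idx = _place_effects(
        rng, island, dist, n_hyper, n_hypo, config.enrichment_odds,
        mu0=mu0, delta=config.delta_effect,
    )
    truth_probes.iloc[hyper_idx, truth_probes.columns.get_loc("direction")] = "hyper"
    truth_probes.iloc[hypo_idx, truth_probes.columns.get_loc("direction")] = "hypo"

    delta = np.zeros(n)
    delta[hyper_idx] = config.delta_effect
    delta[hypo_idx] = -config.delta_effect

    # a subset of the remaining probes varies patient-to-patient (mixture of
    # low/mid/high states) so survival discretization yields populated groups;
    # planted differential probes keep their tight baselines
    free_for_var = delta == 0
    variable = (rng.random(n) < config.frac_variable) & free_for_var
    state_means = np.array([0.12, 0.5, 0.88])
    state_probs = np.array([0.3, 0.45, 0.25])
    states = rng.choice(3, size=(n, n_samples), p=state_probs)
    mu = np.where(variable[:, None], state_means[states], mu0[:, None])

    # per-sample purity: diluted tumors express only a fraction of the effect
    purity = np.ones(n_samples)
    diluted_ids: list[str] = []
    if config.n_diluted > 0:
        if config.n_diluted > nt:
            raise ValidationError("n_diluted exceeds n_tumor", code="config")
        pick = rng.choice(nt, size=config.n_diluted, replace=False)
        purity[pick] = config.dilution_purity
        diluted_ids = [sample_ids[i] for i in pick]

    effect = delta[:, None] * (tumor * purity)[None, :]
    mu = mu + effect

    # SCC-vs-AC layer on probes untouched by the tumor/normal layer
    n_sh = int(round(config.frac_scc_hyper * n))
    n_sl = int(round(config.frac_scc_hypo * n))
    if n_sh + n_sl > 0:
        free = (truth_probes["direction"].to_numpy() == "none") & ~variable
        free_hyper = np.flatnonzero(free & (mu0 + config.delta_effect <= 0.99))
        free_hypo = np.flatnonzero(free & (mu0 - config.delta_effect >= 0.01))
        if n_sh > len(free_hyper) or n_sl > len(free_hypo):
            raise ValidationError(
                "more SCC/AC planted CpGs than eligible probes", code="placement"
            )
        scc_hyper = rng.choice(free_hyper, size=n_sh, replace=False)
        pool_hypo = np.setdiff1d(free_hypo, scc_hyper)
        if n_sl > len(pool_hypo):
            raise ValidationError(
                "more SCC/AC planted CpGs than eligible probes", code="placement"
            )
        scc_hypo = rng.choice(pool_hypo, size=n_sl, replace=False)
        truth_probes.iloc[scc_hyper, truth_probes.columns.get_loc("scc_direction")] = "hyper"
        truth_probes.iloc[scc_hypo, truth_probes.columns.get_loc("scc_direction")] = "hypo"
        is_scc = np.array([h == "SCC" for h in histology])
        scc_delta = np.zeros(n)
        scc_delta[scc_hyper] = config.delta_effect
        scc_delta[scc_hypo] = -config.delta_effect
        mu = mu + scc_delta[:, None] * (is_scc * purity)[None, :]

    truth_probes["true_delta"] = delta  # nominal planted effect (purity 1)

    # smoking layers (tumor-only covariate effects)
    smoker = np.array([None] * n_samples, dtype=object)
    pack_years = np.full(n_samples, np.nan)
    tumor_pos = np.flatnonzero(tumor)
    n_missing_smoke = 1 if nt > config.n_nonsmokers + 1 else 0
    shuffled = rng.permutation(tumor_pos)
    nonsmokers = shuffled[: config.n_nonsmokers]
    missing_smoke = shuffled[config.n_nonsmokers : config.n_nonsmokers + n_missing_smoke]
    smokers = shuffled[config.n_nonsmokers + n_missing_smoke :]
    smoker[nonsmokers] = False
    smoker[smokers] = True
    pack_years[nonsmokers] = 0.0
    pack_years[smokers] = np.round(rng.gamma(4.0, 10.0, size=len(smokers)), 1)

    free = np.flatnonzero(
        (truth_probes["direction"] == "none").to_numpy()
        & (truth_probes["scc_direction"] == "none").to_numpy()
        & ~variable
    )
    if config.n_smoker_cpgs + config.n_packyear_cpgs > len(free):
        raise ValidationError("more covariate CpGs than free probes", code="placement")
    pick = rng.choice(free, size=config.n_smoker_cpgs + config.n_packyear_cpgs, replace=False)
    smoke_idx = pick[: config.n_smoker_cpgs]
    py_idx = pick[config.n_smoker_cpgs :]
    truth_probes.iloc[smoke_idx, truth_probes.columns.get_loc("smoker_effect")] = True
    truth_probes.iloc[py_idx, truth_probes.columns.get_loc("packyear_slope")] = (
        config.packyear_slope
    )
    is_smoker = np.array([s is True for s in smoker])
    if len(smoke_idx):
        sm_delta = np.zeros(n)
        sm_delta[smoke_idx] = config.smoker_delta
        mu = mu + sm_delta[:, None] * is_smoker[None, :]
    if len(py_idx):
        py = np.nan_to_num(pack_years)
        slope = np.zeros(n)
        slope[py_idx] = config.packyear_slope
        mu = mu + slope[:, None] * py[None, :]

    # prognostic CpGs: chosen among patient-variable probes not already planted
    eligible = np.flatnonzero(
        variable
        & (truth_probes["direction"] == "none").to_numpy()
        & (truth_probes["scc_direction"] == "none").to_numpy()
    )
    if config.n_prognostic_cpgs > len(eligible):
        raise ValidationError(
            "more prognostic CpGs than eligible (patient-variable) probes",
            code="placement",
        )
    prog_idx = rng.choice(eligible, size=config.n_prognostic_cpgs, replace=False)
    truth_probes.iloc[prog_idx, truth_probes.columns.get_loc("prognostic")] = True

    # --- draw betas ---
    mu = np.clip(mu, 0.01, 0.99)
    nu = config.beta_precision
    beta = rng.beta(mu * nu, (1.0 - mu) * nu)
    beta_df = pd.DataFrame(beta, index=manifest.index, columns=sample_ids)

    # --- survival from the prognostic CpGs' discretized methylation ---
    from .survival import discretize_beta_array  # local import to avoid cycle

    if len(prog_idx):
        groups = discretize_beta_array(beta[prog_idx][:, tumor])  # (n_prog, nt) in {0,1,2}
        group_score = groups.mean(axis=0)
    else:
        group_score = np.ones(nt)
    hazard_mult = np.exp(config.hazard_log_ratio * group_score)
    rate = config.baseline_hazard * hazard_mult
    t_event = rng.exponential(1.0 / rate)
    survival = np.minimum(t_event, config.censor_horizon)
    event = t_event <= config.censor_horizon
    # keep natural survivals clear of the early-death window so that exactly
    # the two planted post-operative deaths fall at <= 1 month
    survival = np.maximum(survival, 1.1)
    if nt >= 2:
        early = rng.choice(nt, size=2, replace=False)
        survival[early] = np.array([0.5, 1.0])
        event[early] = True
    survival = np.round(survival, 1)

    surv_all = np.full(n_samples, np.nan)
    event_all = np.array([None] * n_samples, dtype=object)
    surv_all[tumor] = survival
    event_all[tumor_pos] = [bool(e) for e in event]

    sheet = pd.DataFrame(
        {
            "tissue": np.where(tumor, "tumor", "normal"),
            "histology": histology,
            "survival_months": surv_all,
            "event": event_all,
            "pack_years": pack_years,
            "smoker": smoker,
            "replicate_group": None,
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    # --- technical replicates ---
    if config.n_replicate_pairs > 0:
        if config.n_replicate_pairs > n_samples:
            raise ValidationError("more replicate pairs than samples", code="config")
        rep_pick = rng.choice(n_samples, size=config.n_replicate_pairs, replace=False)
        for k, pos in enumerate(rep_pick):
            sid = sample_ids[pos]
            rep_id = f"{sid}r"
            group = f"rep{k + 1}"
            noise = rng.normal(0.0, config.replicate_noise_sd, size=n)
            beta_df[rep_id] = np.clip(beta_df[sid].to_numpy() + noise, 0.0, 1.0)
            sheet.loc[sid, "replicate_group"] = group
            row = sheet.loc[sid].copy()
            row["replicate_group"] = group
            sheet.loc[rep_id] = row

    # --- expression matrix ---
    expr = _simulate_expression(config, rng, manifest, truth_probes, beta_df, sheet)

    hazard_all = np.full(n_samples, np.nan)
    hazard_all[tumor_pos] = hazard_mult
    truth_samples = pd.DataFrame(
        {
            "group": np.where(tumor, "tumor", "normal"),
            "hazard_multiplier": hazard_all,
            "diluted": [sample_ids[i] in diluted_ids for i in range(n_samples)],
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )

    return SimulatedDataset(
        beta=beta_df,
        expression=expr,
        sheet=sheet,
        manifest=manifest,
        truth=GroundTruth(probes=truth_probes, samples=truth_samples),
        config=config,
    )


def _place_effects(
    rng: np.random.Generator,
    island: np.ndarray,
    dist: np.ndarray,
    n_hyper: int,
    n_hypo: int,
    odds: float,
    mu0: np.ndarray,
    delta: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted placement of planted effects.

    Hyper effects prefer island / TSS-proximal probes at the configured odds;
    hypo effects prefer non-island (shore) / upstream probes analogously.
    Probes whose baseline cannot absorb the full effect without clipping are
    ineligible for that direction.
    """
    n = len(island)
    proximal = np.abs(dist) <= 500
    w_hyper = np.where(island | proximal, odds, 1.0) * (mu0 + delta <= 0.99)
    w_hypo = np.where(~island & (dist < 0), odds, 1.0) * (mu0 - delta >= 0.01)
    if n_hyper > np.count_nonzero(w_hyper) or n_hyper + n_hypo > n:
        raise ValidationError("more planted hyper CpGs than eligible probes",
                              code="placement")
    hyper_idx = _weighted_pick(rng, w_hyper, n_hyper)
    w = w_hypo.copy()
    w[hyper_idx] = 0.0
    if n_hypo > np.count_nonzero(w):
        raise ValidationError("more planted hypo CpGs than eligible probes",
                              code="placement")
    hypo_idx = _weighted_pick(rng, w, n_hypo)
    return hyper_idx, hypo_idx


def _weighted_pick(rng: np.random.Generator, w: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return np.array([], dtype=int)
    p = w / w.sum()
    return rng.choice(len(w), size=k, replace=False, p=p)


def _simulate_expression(
    config: SimulationConfig,
    rng: np.random.Generator,
    manifest: pd.DataFrame,
    truth_probes: pd.DataFrame,
    beta_df: pd.DataFrame,
    sheet: pd.DataFrame,
) -> ExpressionMatrix:
    """Log2-normal expression with inverse coupling to methylation for a
    fraction of the differentially methylated genes (and the same fraction of
    background genes, so the census is non-degenerate)."""
    genes = sorted(manifest["gene"].unique())
    samples = list(beta_df.columns)
    n_s = len(samples)

    # coupled genes: frac_expr_coupled of genes carrying a planted CpG
    planted_genes = sorted(
        manifest.loc[truth_probes["direction"] != "none", "gene"].unique()
    )
    n_coupled = int(round(config.frac_expr_coupled * len(planted_genes)))
    coupled = set(
        rng.choice(planted_genes, size=n_coupled, replace=False) if n_coupled else []
    )
    # remember coupling at probe level for ground truth
    probe_coupled = manifest["gene"].isin(coupled) & (truth_probes["direction"] != "none")
    truth_probes["expr_coupled"] = probe_coupled.to_numpy()

    gene_first_probe = (
        pd.Series(manifest.index, index=manifest.index)
        .groupby(manifest["gene"])
        .first()
    )
    # coupling follows the gene's planted CpG when present
    planted_first = (
        pd.Series(manifest.index, index=manifest.index)[truth_probes["direction"] != "none"]
        .groupby(manifest.loc[truth_probes["direction"] != "none", "gene"])
        .first()
    )

    rows, probe_ids, probe_genes = [], [], []
    n_probes_per_gene = rng.integers(1, 4, size=len(genes))
    for gi, gene in enumerate(genes):
        base = rng.normal(8.0, 2.0)
        anchor = planted_first.get(gene, gene_first_probe[gene])
        b = beta_df.loc[anchor].to_numpy()
        shift = (
            -config.coupling_slope * (b - b.mean()) if gene in coupled else np.zeros(n_s)
        )
        for k in range(n_probes_per_gene[gi]):
            probe_ids.append(f"ep_{gene}_{k}")
            probe_genes.append(gene)
            rows.append(base + shift + rng.normal(0.0, 1.0, size=n_s))
    values = pd.DataFrame(np.array(rows), index=probe_ids, columns=samples)
    values.index.name = "probe_id"
    return ExpressionMatrix(values=values, probe_gene=pd.Series(probe_genes, index=probe_ids))


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact of a simulated dataset as TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "expression": outdir / "expression.tsv",
        "sheet": outdir / "samples.tsv",
        "manifest": outdir / "manifest.tsv",
        "truth_probes": outdir / "truth_probes.tsv",
        "truth_samples": outdir / "truth_samples.tsv",
    }
    write_beta(ds.beta, paths["beta"])
    write_expression(ds.expression, paths["expression"])
    write_sample_sheet(ds.sheet, paths["sheet"])
    write_manifest(ds.manifest, paths["manifest"])
    ds.truth.probes.to_csv(paths["truth_probes"], sep="\t")
    ds.truth.samples.to_csv(paths["truth_samples"], sep="\t")
    return paths
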