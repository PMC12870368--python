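"""Ground-truth synthetic study generator.

Emulates a farm-clustered hen faecal study: a binary compost-treatment
indicator (Cmp) drives four latent variables — acetate (Ace), butyrate
(Bty) and the genera Romboutsia (Rmb) and Turicibacter (Trc) — through a
configurable linear non-Gaussian structural model.  The latents are embedded
into a Dirichlet-multinomial genus count table (~60 genera) and a lognormal
metabolite concentration table, with farm random intercepts and an
attenuated effect in the short-exposure reference arm.  Every downstream
stage can therefore be scored against known truth.

Default structural noise is uniform (strongly non-Gaussian, bounded), which
satisfies the LiNGAM identifiability prerequisite; a Gaussian family is
available for negative controls and tags the truth object as
non-identifiable so tests assert only on non-Gaussian runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ValidationError
from .tables import FeatureTable, RunConfig, SampleMetadata

LATENTS = ("Cmp", "Ace", "Bty", "Rmb", "Trc")

#: Default treatment DAG: Cmp raises the two SCFAs and lowers the two
#: genera; Rmb feeds Trc and Bty feeds Ace.  Keys are (parent, child).
DEFAULT_EDGES = {
    ("Cmp", "Ace"): 0.8,
    ("Cmp", "Bty"): 0.6,
    ("Cmp", "Rmb"): -0.8,
    ("Cmp", "Trc"): -0.5,
    ("Rmb", "Trc"): 0.5,
    ("Bty", "Ace"): 0.4,
}


@dataclass
class StructuralModel:
    """Linear structural model x_v = sum_parents b * x_parent + noise."""

    variables: tuple
    edges: dict  # (parent, child) -> coefficient
    noise_scales: dict  # variable -> noise SD
    noise_family: str = "uniform"

    def __post_init__(self) -> None:
        for (p, c) in self.edges:
            if p not in self.variables or c not in self.variables:
                raise ValidationError(f"edge ({p}, {c}) references unknown variable")
        for v, s in self.noise_scales.items():
            if s <= 0:
                raise ValidationError(f"noise scale for {v} must be positive")
        if self.noise_family not in ("uniform", "laplace", "gaussian"):
            raise ValidationError(f"unknown noise family {self.noise_family!r}")
        g = nx.DiGraph()
        g.add_nodes_from(self.variables)
        g.add_edges_from(self.edges.keys())
        if not nx.is_directed_acyclic_graph(g):
            raise ValidationError("structural model must be acyclic")
        self._order = list(nx.topological_sort(g))
        # stable order: topological, ties broken by declared variable order
        self._order.sort(key=lambda v: (len(nx.ancestors(g, v)), self.variables.index(v)))
        self._graph = g

    def parents(self, v: str) -> list:
        return list(self._graph.predecessors(v))

    def adjacency(self) -> np.ndarray:
        """B with B[i, j] = coefficient of variable j on variable i."""
        k = len(self.variables)
        b = np.zeros((k, k))
        idx = {v: i for i, v in enumerate(self.variables)}
        for (p, c), w in self.edges.items():
            b[idx[c], idx[p]] = w
        return b


def _draw_noise(rng: np.random.Generator, family: str, scale: float, n: int) -> np.ndarray:
    """Zero-mean noise with standard deviation ``scale``."""
    if family == "uniform":
        half = np.sqrt(3.0) * scale
        return rng.uniform(-half, half, n)
    if family == "laplace":
        return rng.laplace(0.0, scale / np.sqrt(2.0), n)
    return rng.normal(0.0, scale, n)


def generate_sem_sample(
    model: StructuralModel,
    n: int,
    seed: int,
    exogenous: dict | None = None,
) -> pd.DataFrame:
    """Draw ``n`` joint samples from the structural model.

    ``exogenous`` may pin source variables (e.g. the treatment indicator) to
    given per-sample values; pinned variables receive no noise term.
    Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    exogenous = exogenous or {}
    values: dict[str, np.ndarray] = {}
    for v in model._order:
        if v in exogenous:
            col = np.asarray(exogenous[v], dtype=float)
            if col.shape != (n,):
                raise ValidationError(f"exogenous values for {v} must have length {n}")
            values[v] = col
            continue
        total = _draw_noise(rng, model.noise_family, model.noise_scales.get(v, 1.0), n)
        for p in model.parents(v):
            total = total + model.edges[(p, v)] * values[p]
        values[v] = total
    return pd.DataFrame({v: values[v] for v in model.variables})


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for downstream scoring."""

    model: StructuralModel
    planted_taxa: dict  # taxon id -> signed CLR effect of treatment
    planted_metabolites: dict  # metabolite id -> signed log effect
    latent_taxa: dict  # latent name -> taxon id (latent added on log scale)
    latent_metabolites: dict  # latent name -> metabolite id
    farm_sd: float
    ref_effect_fraction: float
    seed: int
    lingam_identifiable: bool = True
    notes: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "variables": list(self.model.variables),
            "edges": {f"{p}->{c}": w for (p, c), w in self.model.edges.items()},
            "noise_family": self.model.noise_family,
            "noise_scales": dict(self.model.noise_scales),
            "planted_taxa": dict(self.planted_taxa),
            "planted_metabolites": dict(self.planted_metabolites),
            "latent_taxa": dict(self.latent_taxa),
            "latent_metabolites": dict(self.latent_metabolites),
            "farm_sd": self.farm_sd,
            "ref_effect_fraction": self.ref_effect_fraction,
            "seed": self.seed,
            "lingam_identifiable": self.lingam_identifiable,
        }


class StudyData(NamedTuple):
    counts: FeatureTable
    metabolites: FeatureTable
    metadata: SampleMetadata
    truth: SyntheticTruth


METABOLITE_NAMES = (
    "acetate",
    "butyrate",
    "propionate",
    "lactate",
    "succinate",
    "formate",
    "valerate",
    "isobutyrate",
)


def default_structural_model(noise_family: str = "uniform") -> StructuralModel:
    # SCFA pools swing more between birds than genus abundances do on the
    # log scale, so the metabolite latents carry wider structural noise
    scales = {"Cmp": 1.0, "Ace": 0.5, "Bty": 0.5, "Rmb": 0.3, "Trc": 0.3}
    return StructuralModel(LATENTS, dict(DEFAULT_EDGES), scales, noise_family)


def generate_study(config: RunConfig | None = None, seed: int = 42) -> StudyData:
    """Generate counts, metabolite concentrations, metadata and truth.

    Farms are nested in arms (HS-Comp / HS-CON / Ref); each farm contributes
    ``samples_per_farm`` faecal samples split evenly across a pre phase
    (before administration) and a post phase.  The treatment indicator is 1
    for HS-Comp post samples, ``ref_effect_fraction`` for Ref post samples
    (short exposure) and 0 otherwise.
    """
    config = config or RunConfig.defaults()
    sim = {**RunConfig.defaults().section("simulate"), **config.section("simulate")}
    n_taxa = int(sim["n_taxa"])
    n_met = int(sim["n_metabolites"])
    farms = (
        [("Comp%d" % i, "HS-Comp") for i in range(1, int(sim["farms_comp"]) + 1)]
        + [("Con%d" % i, "HS-CON") for i in range(1, int(sim["farms_con"]) + 1)]
        + [("Ref%d" % i, "Ref") for i in range(1, int(sim["farms_ref"]) + 1)]
    )
    n_arm_farms = {"HS-Comp": int(sim["farms_comp"]), "HS-CON": int(sim["farms_con"])}
    if min(n_arm_farms.values()) < 2:
        raise ValidationError("DID needs at least 2 farms per contrasted arm")
    spf = int(sim["samples_per_farm"])
    if spf < 2:
        raise ValidationError("need at least 2 samples per farm (one per phase)")
    depth_mean = float(sim["depth_mean"])
    if depth_mean <= 0:
        raise ValidationError("sequencing depth must be positive")
    conc = float(sim["dirichlet_concentration"])
    farm_sd = float(sim["farm_sd"])
    ref_frac = float(sim["ref_effect_fraction"])
    noise_family = str(sim["noise_family"])

    effect_scale = float(sim.get("effect_scale", 1.0))
    model = default_structural_model(noise_family)
    if effect_scale != 1.0:
        model = StructuralModel(
            model.variables,
            {e: w * effect_scale for e, w in model.edges.items()},
            model.noise_scales,
            noise_family,
        )

    rng = np.random.default_rng(seed)

    # -- design ------------------------------------------------------------
    rows = []
    for farm, arm in farms:
        for k in range(spf):
            phase = "pre" if k < spf // 2 else "post"
            rows.append((f"{farm}_s{k + 1}", farm, arm, phase))
    meta = pd.DataFrame(rows, columns=["sample_id", "farm", "arm", "phase"]).set_index(
        "sample_id"
    )
    meta["age_weeks"] = np.where(meta["phase"] == "pre", 18, 24)
    n = len(meta)

    cmp_value = np.where(
        (meta["arm"] == "HS-Comp") & (meta["phase"] == "post"),
        1.0,
        np.where((meta["arm"] == "Ref") & (meta["phase"] == "post"), ref_frac, 0.0),
    )

    latents = generate_sem_sample(
        model, n, seed=int(rng.integers(2**31 - 1)), exogenous={"Cmp": cmp_value}
    )
    latents.index = meta.index

    # -- taxa --------------------------------------------------------------
    taxa = [f"genus_{i:02d}" for i in range(1, n_taxa + 1)]
    planted_direct = {}
    latent_taxa = {"Rmb": "genus_01", "Trc": "genus_02"}
    taxa[0] = "genus_01_Romboutsia_like"
    taxa[1] = "genus_02_Turicibacter_like"
    taxa[2] = "genus_03_Lactobacillus_like"
    taxa[3] = "genus_04_Escherichia_like"
    latent_taxa = {"Rmb": taxa[0], "Trc": taxa[1]}
    planted_direct[taxa[2]] = float(sim.get("lacto_effect", 2.0)) * effect_scale
    planted_direct[taxa[3]] = float(sim.get("escherichia_effect", -2.0)) * effect_scale
    # latent constructs are unit-scale; one latent unit maps to ``gain`` CLR
    # units of its genus, so a planted shift is a severalfold abundance change
    gain = float(sim.get("taxon_embedding_gain", 2.0))

    # lognormal baseline spectrum: a few dominant genera, long rare tail
    base_log = rng.normal(0.0, 1.5, n_taxa)
    # planted genera are dominant community members (the Romboutsia /
    # Turicibacter analogues sit in the >=5% abundance band hen faeces
    # panels report), which also keeps their counts informative after the
    # planted depletion
    base_log[:4] = 2.0
    farm_names = [f for f, _ in farms]
    farm_eff_taxa = {
        f: rng.normal(0.0, farm_sd, n_taxa) for f in farm_names
    }  # per-taxon farm intercepts (log scale)

    log_comp = np.tile(base_log, (n, 1))
    for i, sid in enumerate(meta.index):
        log_comp[i] += farm_eff_taxa[meta.loc[sid, "farm"]]
    idx = {t: j for j, t in enumerate(taxa)}
    for latent, taxon in latent_taxa.items():
        log_comp[:, idx[taxon]] += gain * latents[latent].to_numpy()
    for taxon, eff in planted_direct.items():
        log_comp[:, idx[taxon]] += eff * cmp_value

    comp = np.exp(log_comp)
    comp /= comp.sum(axis=1, keepdims=True)
    depths = rng.poisson(depth_mean, n)
    depths = np.maximum(depths, 1)
    counts = np.empty((n, n_taxa), dtype=int)
    for i in range(n):
        p = rng.dirichlet(conc * comp[i])
        counts[i] = rng.multinomial(depths[i], p)
    counts_table = FeatureTable(
        pd.DataFrame(counts, index=meta.index, columns=taxa),
        scale="counts",
        feature_kind="taxon",
    )

    # -- metabolites -------------------------------------------------------
    met_names = list(METABOLITE_NAMES[:n_met])
    latent_met = {"Ace": "acetate", "Bty": "butyrate"}
    base_met = rng.normal(2.0, 0.5, n_met)  # log-mmol scale
    farm_eff_met = {f: rng.normal(0.0, farm_sd, n_met) for f in farm_names}
    log_conc = np.tile(base_met, (n, 1)) + rng.normal(0.0, 0.2, (n, n_met))
    for i, sid in enumerate(meta.index):
        log_conc[i] += farm_eff_met[meta.loc[sid, "farm"]]
    midx = {m: j for j, m in enumerate(met_names)}
    for latent, met in latent_met.items():
        log_conc[:, midx[met]] += latents[latent].to_numpy()
    met_table = FeatureTable(
        pd.DataFrame(np.exp(log_conc), index=meta.index, columns=met_names),
        scale="concentration",
        feature_kind="metabolite",
    )

    # total treatment effects on the planted taxa (direct + via latents)
    total_eff = dict(planted_direct)
    b = model.edges
    total_eff[latent_taxa["Rmb"]] = gain * b[("Cmp", "Rmb")]
    total_eff[latent_taxa["Trc"]] = gain * (
        b[("Cmp", "Trc")] + b[("Rmb", "Trc")] * b[("Cmp", "Rmb")]
    )
    met_eff = {
        "acetate": b[("Cmp", "Ace")] + b[("Bty", "Ace")] * b[("Cmp", "Bty")],
        "butyrate": b[("Cmp", "Bty")],
    }

    truth = SyntheticTruth(
        model=model,
        planted_taxa=total_eff,
        planted_metabolites=met_eff,
        latent_taxa=latent_taxa,
        latent_metabolites=latent_met,
        farm_sd=farm_sd,
        ref_effect_fraction=ref_frac,
        seed=seed,
        lingam_identifiable=noise_family != "gaussian",
    )
    metadata = SampleMetadata(meta)
    return StudyData(counts_table, met_table, metadata, truth)
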