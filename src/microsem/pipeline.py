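"""Staged pipeline: simulate -> preprocess -> did -> select -> efa -> sem
-> mediate -> lingam -> report.

Stages communicate only through files under the output directory, so any
prefix of the canonical order can be re-run and audited; every stage
derives its own seed deterministically from the global seed and the stage
name, and all numeric text output is pinned to 12 significant digits, so a
re-run with the same config and seed is byte-identical.

The analysis chain past the DID screen restricts to the HS-Comp and HS-CON
arms, with the binary treatment item ("Compost_ex") marking treated-arm
post-administration samples; the short-exposure Ref arm enters only the
reference DID contrast.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import causal, did, efa, features, preprocess, sem
from ._util import derive_seed
from .errors import DependencyError, ValidationError
from .simulate import generate_study
from .tables import (
    RunConfig,
    read_feature_table,
    read_metadata,
    write_results,
    write_table,
)

__version__ = "0.1.0"

STAGES = (
    "simulate",
    "preprocess",
    "did",
    "select",
    "efa",
    "sem",
    "mediate",
    "lingam",
    "report",
)

TREATMENT_ITEM = "Compost_ex"


@dataclass
class RunManifest:
    """Machine-readable record of a pipeline run."""

    config_hash: str
    seed: int
    version: str = __version__
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, outputs: list, seed: int, elapsed: float) -> None:
        self.stages[stage] = {
            "status": "done",
            "outputs": sorted(str(o) for o in outputs),
            "seed": seed,
            "wall_seconds": round(elapsed, 3),
        }

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stages": self.stages,
        }

    def save(self, out_dir: Path) -> None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def load(cls, out_dir: Path) -> "RunManifest":
        with open(Path(out_dir) / "manifest.json") as fh:
            obj = json.load(fh)
        m = cls(obj["config_hash"], obj["seed"], obj["version"])
        m.stages = obj["stages"]
        return m


def config_hash(config: RunConfig) -> str:
    blob = yaml.safe_dump(config.sections, sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _need(out_dir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (out_dir / name).exists():
            raise DependencyError(
                f"stage '{stage}' needs {name}; run its upstream stage first"
            )


def _analysis_frame(out_dir: Path) -> tuple[pd.DataFrame, pd.Series]:
    """Combined CLR/log values for the HS-Comp and HS-CON arms plus the
    binary treatment item."""
    combined = pd.read_csv(out_dir / "combined.tsv", sep="\t", index_col=0)
    meta = read_metadata(out_dir / "metadata.tsv").data.loc[combined.index]
    keep = meta["arm"].isin(["HS-Comp", "HS-CON"])
    frame = combined[keep.to_numpy()]
    meta = meta[keep.to_numpy()]
    label = (
        ((meta["arm"] == "HS-Comp") & (meta["phase"] == "post"))
        .astype(int)
        .rename(TREATMENT_ITEM)
    )
    return frame, label


# ---------------------------------------------------------------------------
# stage implementations


def _stage_simulate(out_dir: Path, config: RunConfig, seed: int) -> list:
    study = generate_study(config, seed=seed)
    study.counts.write(out_dir / "counts.tsv")
    study.metabolites.write(out_dir / "metabolites.tsv")
    study.metadata.write(out_dir / "metadata.tsv")
    with open(out_dir / "truth.json", "w") as fh:
        json.dump(study.truth.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ["counts.tsv", "metabolites.tsv", "metadata.tsv", "truth.json"]


def _stage_preprocess(out_dir: Path, config: RunConfig, seed: int) -> list:
    _need(out_dir, "preprocess", "counts.tsv", "metabolites.tsv", "metadata.tsv")
    counts = read_feature_table(out_dir / "counts.tsv", "counts", "taxon")
    mets = read_feature_table(out_dir / "metabolites.tsv", "concentration", "metabolite")
    pc = float(config.get("preprocess", "pseudocount", 0.5))
    off = float(config.get("preprocess", "log_offset", 0.5))
    clr = preprocess.clr_transform(counts, pc)
    logmet = preprocess.log_transform(mets, off)
    clr.write(out_dir / "clr.tsv")
    logmet.write(out_dir / "logmet.tsv")
    combined = pd.concat([clr.data, logmet.data], axis=1)
    write_table(combined, out_dir / "combined.tsv")
    write_table(preprocess.alpha_diversity(counts).to_frame(), out_dir / "diversity.tsv")
    rows = []
    for col in combined.columns:
        res = preprocess.normality_test(combined[col], "shapiro")
        rows.append({"feature": col, **res})
    write_table(pd.DataFrame(rows).set_index("feature"), out_dir / "normality.tsv")
    return ["clr.tsv", "logmet.tsv", "combined.tsv", "diversity.tsv", "normality.tsv"]


def _stage_did(out_dir: Path, config: RunConfig, seed: int) -> list:
    _need(out_dir, "did", "clr.tsv", "logmet.tsv", "metadata.tsv")
    clr = read_feature_table(out_dir / "clr.tsv", "clr", "taxon")
    logmet = read_feature_table(out_dir / "logmet.tsv", "log", "metabolite")
    meta = read_metadata(out_dir / "metadata.tsv")
    alpha = float(config.get("did", "alpha", 0.05))
    fdr_cut = float(config.get("did", "fdr_cut", 0.1))
    n_perm = int(config.get("did", "n_perm", 10000))
    runs = {
        "did_taxa.tsv": (clr, ("HS-Comp", "HS-CON")),
        "did_taxa_ref.tsv": (clr, ("HS-Comp", "Ref")),
        "did_metabolites.tsv": (logmet, ("HS-Comp", "HS-CON")),
    }
    outputs = []
    for name, (table, contrast) in runs.items():
        res = did.did_test(
            table, meta, contrast=contrast, alpha=alpha, fdr_cut=fdr_cut,
            n_perm=n_perm, seed=derive_seed(seed, name),
        )
        write_results(res, out_dir / name, "tsv")
        outputs.append(name)
    return outputs


def _stage_select(out_dir: Path, config: RunConfig, seed: int) -> list:
    _need(out_dir, "select", "combined.tsv", "metadata.tsv")
    frame, label = _analysis_frame(out_dir)
    binary = preprocess.binarize_by_median(frame)
    bm = binary.data.copy()
    # complement ("low") items let depletion under treatment form rule
    # antecedents; otherwise only enriched features could ever be mined
    for col in binary.data.columns:
        bm[f"{col}__low"] = 1 - binary.data[col]
    bm[TREATMENT_ITEM] = label.loc[bm.index]
    binary_full = preprocess.BinaryMatrix(bm, binary.thresholds, binary.dropped)
    sel = config.section("select")
    max_cand = int(sel.get("max_candidates", 20))
    ruleset = features.mine_association_rules(
        binary_full,
        TREATMENT_ITEM,
        min_support=float(sel.get("min_support", 0.2)),
        min_confidence=float(sel.get("min_confidence", 0.6)),
        max_candidates=2 * max_cand,  # high/low items collapse to features below
    )
    candidates = []
    for item in ruleset.candidates:
        base = item.removesuffix("__low")
        if base not in candidates:
            candidates.append(base)
    candidates = candidates[:max_cand]
    if len(candidates) < max_cand:
        # pad sparse rule output with the strongest marginal AUC features so
        # the supervised scorers always see a full candidate slate
        auc_rank = sorted(
            (c for c in frame.columns if c not in candidates),
            key=lambda c: (-abs(features.roc_auc(frame[c], label) - 0.5), c),
        )
        candidates += auc_rank[: max_cand - len(candidates)]
    scores = features.score_candidates(
        frame[candidates],
        label.to_numpy(),
        seed=seed,
        n_trees=int(sel.get("n_trees", 1000)),
        n_rounds=int(sel.get("n_rounds", 100)),
        max_depth=int(sel.get("max_depth", 3)),
        learning_rate=float(sel.get("learning_rate", 0.3)),
    )
    top = features.consensus_select(scores, int(sel.get("top_k", 8)))
    write_results(ruleset, out_dir / "rules.tsv", "tsv")
    write_results(scores, out_dir / "feature_scores.tsv", "tsv")
    with open(out_dir / "selected_features.json", "w") as fh:
        json.dump({"candidates": candidates, "selected": top}, fh, indent=2)
        fh.write("\n")
    return ["rules.tsv", "feature_scores.tsv", "selected_features.json"]


def _selected(out_dir: Path) -> list:
    with open(out_dir / "selected_features.json") as fh:
        return json.load(fh)["selected"]


def _stage_efa(out_dir: Path, config: RunConfig, seed: int) -> list:
    _need(out_dir, "efa", "selected_features.json", "combined.tsv")
    frame, label = _analysis_frame(out_dir)
    cols = _selected(out_dir)
    data = frame[cols].copy()
    data[TREATMENT_ITEM] = label.to_numpy()
    rho, _ = preprocess.spearman_matrix(data)
    max_nf = min(int(config.get("efa", "max_nfactors", 5)), len(data.columns) // 2)
    curve, best = efa.vss_curve(rho, max_nf, int(config.get("efa", "vss_complexity", 1)))
    result = efa.fit_efa(
        rho, best, rotation="auto", kappa=float(config.get("efa", "kappa", 4)),
    )
    result.vss_curve = curve
    write_results(result, out_dir / "efa_loadings.tsv", "tsv")
    write_results(result, out_dir / "efa.json", "json")
    write_table(rho, out_dir / "component_spearman.tsv")
    return ["efa_loadings.tsv", "efa.json", "component_spearman.tsv"]


def _sem_variables(out_dir: Path) -> list:
    cols = [c for c in _selected(out_dir) if c != TREATMENT_ITEM][:4]
    return [TREATMENT_ITEM] + cols


def _sem_data(out_dir: Path) -> pd.DataFrame:
    frame, label = _analysis_frame(out_dir)
    data = frame.copy()
    data[TREATMENT_ITEM] = label.to_numpy().astype(float)
    return data


def _stage_sem(out_dir: Path, config: RunConfig, seed: int) -> list:
    _need(out_dir, "sem", "selected_features.json", "combined.tsv")
    variables = _sem_variables(out_dir)
    data = _sem_data(out_dir)[variables]
    rho, _ = preprocess.spearman_matrix(data)
    comps = variables[1:]
    # skeleton: treatment feeds every component; component pairs with
    # |Spearman rho| > 0.4 get an (orientable) edge
    base = [(TREATMENT_ITEM, c) for c in comps]
    orientable = [
        (a, b)
        for a, b in zip(*np.triu_indices(len(comps), k=1))
    ]
    pairs = [
        (comps[a], comps[b])
        for a, b in orientable
        if abs(rho.loc[comps[a], comps[b]]) > 0.4
    ]
    fixed_var = {TREATMENT_ITEM: float(data[TREATMENT_ITEM].var(ddof=1))}
    candidates = []
    from itertools import product as _product

    for keep_mask in _product((0, 1), repeat=len(pairs)):
        kept = [p for p, k in zip(pairs, keep_mask) if k]
        for m in sem.enumerate_orientations(
            variables, kept, exogenous=TREATMENT_ITEM, cap=200
        ):
            candidates.append(
                sem.PathModel(
                    tuple(variables),
                    tuple(base) + m.edges,
                    (),
                    fixed_var,
                )
            )
        if len(candidates) >= 200:
            break
    candidates = candidates[:200]
    result = sem.enumerate_and_select(candidates, data)
    write_results(result, out_dir / "sem_ranking.tsv", "tsv")
    outputs = ["sem_ranking.tsv"]
    if result.selected is not None:
        boot = sem.bootstrap_se(
            result.selected.model,
            data,
            n_boot=int(config.get("sem", "n_boot", 1000)),
            seed=derive_seed(seed, "sem_boot"),
        )
        result.selected.boot_se = boot
        write_results(result.selected, out_dir / "sem_selected.json", "json")
        write_results(result.selected, out_dir / "sem_selected.dot", "dot")
        outputs += ["sem_selected.json", "sem_selected.dot"]
    # per-component arm comparison among post-phase samples
    meta = read_metadata(out_dir / "metadata.tsv").data.loc[data.index]
    post = meta["phase"] == "post"
    rows = []
    for comp in comps:
        res = sem.group_compare(data.loc[post, comp], meta.loc[post, "arm"])
        rows.append({"component": comp, **{k: v for k, v in res.items() if k != "arms"}})
    write_table(pd.DataFrame(rows).set_index("component"), out_dir / "group_tests.tsv")
    outputs.append("group_tests.tsv")
    return outputs


def _stage_mediate(out_dir: Path, config: RunConfig, seed: int) -> list:
    _need(out_dir, "mediate", "selected_features.json", "combined.tsv")
    variables = _sem_variables(out_dir)
    data = _sem_data(out_dir)[variables]
    comps = variables[1:]
    n_sims = int(config.get("causal", "n_sims", 1000))
    rows, blobs = [], []
    for mediator in comps:
        for outcome in comps:
            if mediator == outcome:
                continue
            res = causal.mediate(
                data, TREATMENT_ITEM, mediator, outcome,
                n_sims=n_sims,
                seed=derive_seed(seed, f"med:{mediator}->{outcome}"),
            )
            rows.append(
                {
                    "mediator": mediator,
                    "outcome": outcome,
                    "acme": res.acme,
                    "acme_lo": res.ci["acme"][0],
                    "acme_hi": res.ci["acme"][1],
                    "ade": res.ade,
                    "total": res.total,
                    "prop_mediated": res.prop_mediated,
                    "acme_significant": res.significant("acme"),
                }
            )
            blobs.append(res.to_dict())
    frame = pd.DataFrame(rows).set_index(["mediator", "outcome"])
    write_table(frame, out_dir / "mediation.tsv")
    with open(out_dir / "mediation.json", "w") as fh:
        json.dump(blobs, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return ["mediation.tsv", "mediation.json"]


def _stage_lingam(out_dir: Path, config: RunConfig, seed: int) -> list:
    _need(out_dir, "lingam", "selected_features.json", "combined.tsv")
    variables = _sem_variables(out_dir)
    data = _sem_data(out_dir)[variables]
    order, adjacency = causal.direct_lingam(data)
    with open(out_dir / "lingam_order.json", "w") as fh:
        json.dump({"order": order}, fh, indent=2)
        fh.write("\n")
    write_table(adjacency, out_dir / "lingam_adjacency.tsv")
    comps = variables[1:]
    posterior = causal.bayes_lingam(data[comps], seed=derive_seed(seed, "bayes"))
    write_results(posterior, out_dir / "dag_posterior.json", "json")
    write_results(posterior, out_dir / "dag_posterior.dot", "dot")
    return [
        "lingam_order.json",
        "lingam_adjacency.tsv",
        "dag_posterior.json",
        "dag_posterior.dot",
    ]


def _stage_report(out_dir: Path, config: RunConfig, seed: int) -> list:
    render_report(out_dir)
    return ["report.md", "summary.json"]


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "did": _stage_did,
    "select": _stage_select,
    "efa": _stage_efa,
    "sem": _stage_sem,
    "mediate": _stage_mediate,
    "lingam": _stage_lingam,
    "report": _stage_report,
}


def run_pipeline(
    config: RunConfig | str | Path | None = None,
    out_dir: str | Path = "microsem_out",
    stages: tuple = STAGES,
    seed_override: int | None = None,
) -> RunManifest:
    """Execute the requested stages in canonical order."""
    if config is None:
        config = RunConfig.defaults()
    elif not isinstance(config, RunConfig):
        config = RunConfig.from_yaml(config)
    unknown = [s for s in stages if s not in STAGES]
    if unknown:
        raise ValidationError(f"unknown stages: {unknown}")
    stages = tuple(s for s in STAGES if s in stages)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(
        seed_override
        if seed_override is not None
        else config.get("seed", "global", 42)
    )
    manifest = (
        RunManifest.load(out_dir)
        if (out_dir / "manifest.json").exists()
        else RunManifest(config_hash(config), seed)
    )
    manifest.config_hash = config_hash(config)
    manifest.seed = seed
    config.to_yaml(out_dir / "config_used.yaml")
    for stage in stages:
        t0 = time.perf_counter()
        stage_seed = derive_seed(seed, stage)
        outputs = _STAGE_FUNCS[stage](out_dir, config, stage_seed)
        manifest.record(stage, outputs, stage_seed, time.perf_counter() - t0)
        manifest.save(out_dir)
    return manifest


# ---------------------------------------------------------------------------
# report


def _maybe(out_dir: Path, name: str):
    p = out_dir / name
    return p if p.exists() else None


def render_report(out_dir: str | Path) -> dict:
    """Assemble the run report (markdown + summary JSON) from artifacts.

    A pure function of the files on disk: regenerating without re-running
    stages produces identical content.
    """
    out_dir = Path(out_dir)
    if not (out_dir / "manifest.json").exists():
        raise DependencyError("no manifest.json; run at least one stage first")
    manifest = RunManifest.load(out_dir)
    lines = ["# microsem run report", ""]
    summary: dict = {"stages_run": sorted(manifest.stages)}
    if not manifest.stages:
        lines.append("No stages run.")
    if _maybe(out_dir, "did_taxa.tsv"):
        tab = pd.read_csv(out_dir / "did_taxa.tsv", sep="\t", index_col=0)
        sig = tab[tab["significant"]]
        lines += [
            "## DID screen (taxa, Comp vs CON)",
            "",
            f"{len(sig)} / {len(tab)} features significant "
            f"(p < alpha and FDR < cutoff).",
            "",
            "```\n" + sig.head(15).to_string() + "\n```",
            "",
        ]
        summary["did_significant"] = sig.index.tolist()
    if _maybe(out_dir, "feature_scores.tsv"):
        sc = pd.read_csv(out_dir / "feature_scores.tsv", sep="\t", index_col=0)
        lines += ["## Feature-selection bubble table", "", "```\n" + sc.to_string() + "\n```", ""]
        summary["selected_features"] = _selected(out_dir)
    if _maybe(out_dir, "efa_loadings.tsv"):
        lo = pd.read_csv(out_dir / "efa_loadings.tsv", sep="\t", index_col=0)
        lines += ["## EFA loadings (heat-map source)", "", "```\n" + lo.to_string() + "\n```", ""]
    if _maybe(out_dir, "sem_ranking.tsv"):
        rk = pd.read_csv(out_dir / "sem_ranking.tsv", sep="\t", index_col=0)
        chosen = rk.index[rk["selected"]].tolist() if "selected" in rk else []
        if chosen:
            lines += ["## SEM ledger", "", f"Selected model: `{chosen[0]}`", ""]
            summary["sem_selected"] = chosen[0]
        else:
            lines += ["## SEM ledger", "", "No model passed the ledger.", ""]
            summary["sem_selected"] = None
        keep = [c for c in ("chisq_scaled", "p_sc", "cfi_robust", "rmsea",
                            "srmr", "gfi", "agfi", "aic", "stage1") if c in rk]
        lines += ["```\n" + rk[keep].head(10).to_string() + "\n```", ""]
    if _maybe(out_dir, "mediation.tsv"):
        med = pd.read_csv(out_dir / "mediation.tsv", sep="\t")
        lines += ["## Mediation (ACME / ADE)", "", "```\n" + med.to_string(index=False) + "\n```", ""]
    if _maybe(out_dir, "dag_posterior.json"):
        with open(out_dir / "dag_posterior.json") as fh:
            post = json.load(fh)
        lines += [
            "## DAG posterior",
            "",
            f"Top-{post['top_k']} cumulative mass: {100 * post['top_mass']:.2f}%",
            "",
        ]
        summary["dag_top_mass"] = post["top_mass"]
    if _maybe(out_dir, "truth.json"):
        with open(out_dir / "truth.json") as fh:
            truth = json.load(fh)
        planted = set(truth["planted_taxa"]) | set(truth["planted_metabolites"])
        scorecard = {}
        if "selected_features" in summary:
            hits = planted & set(summary["selected_features"])
            scorecard["planted_in_top_k"] = sorted(hits)
            scorecard["recall_top_k"] = len(hits) / len(planted)
        if "did_significant" in summary:
            taxa_hits = set(truth["planted_taxa"]) & set(summary["did_significant"])
            scorecard["planted_taxa_flagged_by_did"] = sorted(taxa_hits)
        summary["recovery_scorecard"] = scorecard
        if scorecard:
            lines += [
                "## Recovery scorecard (synthetic truth available)",
                "",
                "```json",
                json.dumps(scorecard, indent=2, sort_keys=True),
                "```",
                "",
            ]
    (out_dir / "report.md").write_text("\n".join(lines))
    with open(out_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return summary
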