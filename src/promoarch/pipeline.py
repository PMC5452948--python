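"""One-command orchestration of the full workflow.

split → scan → motif deduplication → ORI selection → feature matrix → FCBF
filter → GA + fivefold CV → model JSON → held-out ranking → enrichment report.
Every stage is also callable standalone through the library; this module wires
them together from a single YAML/dict config, logs each stage, and writes a
manifest with digests of every artifact. Re-running with an identical config
reproduces a byte-identical model JSON.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as paio
from .features import (FeatureConfig, FeatureDescriptor,
                       build_feature_matrix, correlation_filter,
                       enumerate_candidate_features)
from .ga import GAConfig, cross_validate
from .motifs import build_occurrence_index, deduplicate_motifs, select_overrepresented
from .promoters import split_gene_sets
from .scoring import Model
from .synthetic_data import (ArchitectureSpec, PlantedFeature, generate_background_regions,
                             generate_cohort, generate_pwm)
from .validation import enrichment_of_top, adjust_fdr, fscore_permutation_pvalue, rank_genome

log = logging.getLogger("promoarch.pipeline")


class ConfigError(ValueError):
    pass


class DataError(ValueError):
    pass


class NoModelError(RuntimeError):
    pass


DEFAULTS = {
    "seed": 0,
    "scan": {"threshold_fraction": 0.8},
    "dedup": {"p_threshold": 0.001, "n_null": 500},
    "ori": {"p_threshold": 0.01, "n_perm": 10_000},
    "features": {"delta": 0.0},
    "ga": {"mutation_prob": 0.05, "max_iters": 10_000, "fscore_stop": 0.8,
           "early_stop_pos_fraction": 0.5, "early_stop_neg_quantile": 0.9,
           "selection": "tournament_k2", "elitism": 1, "folds": 5},
    "validation": {"n_top": 100, "n_perm": 10_000, "fdr_threshold": 0.01},
}


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict = field(default_factory=dict)  # stage -> {time_s, outputs: {path: sha256}}
    stop_reasons: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"config": self.config, "seed": self.seed, "stages": self.stages,
                "stop_reasons": self.stop_reasons}


def _sha256(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _merged(config: dict) -> dict:
    out = json.loads(json.dumps(DEFAULTS))
    for k, v in config.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k].update(v)
        else:
            out[k] = v
    return out


def load_config(path_or_dict) -> dict:
    if isinstance(path_or_dict, dict):
        return _merged(path_or_dict)
    with open(path_or_dict) as fh:
        return _merged(yaml.safe_load(fh))


def _validate_config(cfg: dict) -> None:
    if "synthetic" in cfg:
        syn = cfg["synthetic"]
        for key in ("motifs", "planted"):
            if key not in syn:
                raise ConfigError(f"synthetic config missing {key!r}")
        return
    if "inputs" not in cfg:
        raise ConfigError("config needs a 'synthetic' or an 'inputs' block")
    inputs = cfg["inputs"]
    for key in ("promoters_fasta", "pwms_jaspar", "positive_list", "control_list",
                "background_fasta"):
        if key not in inputs:
            raise ConfigError(f"inputs config missing {key!r}")


def run_pipeline(config, outdir) -> RunManifest:
    """Execute the full workflow; returns the manifest (also written as JSON)."""
    cfg = load_config(config)
    _validate_config(cfg)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    manifest = RunManifest(config=cfg, seed=seed)

    def stage(name):
        t0 = time.time()

        def done(**outputs):
            manifest.stages[name] = {
                "time_s": round(time.time() - t0, 3),
                "outputs": {str(p): _sha256(p) for p in outputs.values()},
            }
            log.info("stage %s done in %.2fs", name, time.time() - t0)
        return done

    # -- stage: inputs -------------------------------------------------------
    done = stage("inputs")
    if "synthetic" in cfg:
        pwms, pos, ctrl, background, val_records, expressed = _synthetic_inputs(cfg, seed)
    else:
        pwms, pos, ctrl, background, val_records, expressed = _file_inputs(cfg)
    promoters = {p.gene_id: p for p in pos + ctrl}
    fa = outdir / "promoters.fa"
    paio.write_fasta([(p.gene_id, p.seq) for p in pos + ctrl], fa)
    mj = outdir / "motifs.jaspar"
    paio.write_jaspar(pwms, mj)
    done(promoters=fa, motifs=mj)

    # -- stage: split --------------------------------------------------------
    done = stage("split")
    split = split_gene_sets([p.gene_id for p in pos], [p.gene_id for p in ctrl], seed)
    sp = outdir / "split.json"
    sp.write_text(json.dumps(split.to_dict(), indent=2, sort_keys=True) + "\n")
    done(split=sp)

    # -- stage: motif selection (dedup + ORI) -------------------------------
    done = stage("motif_selection")
    tf = float(cfg["scan"]["threshold_fraction"])
    pwms = deduplicate_motifs(pwms, p_threshold=float(cfg["dedup"]["p_threshold"]),
                              n_null=int(cfg["dedup"]["n_null"]), seed=seed)
    mp_promoters = [promoters[g] for g in sorted(split.motif_prediction)]
    universe = [promoters[g] for g in sorted(promoters)]
    selected = select_overrepresented(
        pwms, mp_promoters, universe, background,
        p_threshold=float(cfg["ori"]["p_threshold"]),
        n_perm=int(cfg["ori"]["n_perm"]), seed=seed, threshold_fraction=tf)
    if not selected:
        raise NoModelError("no motif passed the overrepresentation test")
    ms = outdir / "selected_motifs.txt"
    ms.write_text("".join(f"{m.name}\n" for m in selected))
    done(selected=ms)

    # -- stage: scan ---------------------------------------------------------
    done = stage("scan")
    occ_index = build_occurrence_index(selected, pos + ctrl, threshold_fraction=tf)
    ob = outdir / "occurrences.bed"
    paio.write_occurrences_bed([o for g in sorted(occ_index) for o in occ_index[g]], ob)
    done(occurrences=ob)

    # -- stage: feature matrix + filter -------------------------------------
    done = stage("features")
    fconfig = FeatureConfig()
    features = enumerate_candidate_features([m.name for m in selected], fconfig)
    matrix_fc = build_feature_matrix(features, occ_index,
                                     split.feature_computation, split.control_feature,
                                     fconfig)
    kept = correlation_filter(matrix_fc, delta=float(cfg["features"]["delta"]))
    if not kept:
        raise NoModelError("the correlation filter removed every feature")
    mt = outdir / "matrix.tsv"
    matrix_fc.restrict_features(kept).to_tsv(mt)
    kf = outdir / "kept_features.txt"
    kf.write_text("".join(f"{f}\n" for f in kept))
    done(matrix=mt, kept=kf)

    # -- stage: GA + cross-validation ----------------------------------------
    done = stage("train")
    ga_cfg_d = dict(cfg["ga"])
    k = int(ga_cfg_d.pop("folds", 5))
    ga_cfg = GAConfig(seed=seed, **ga_cfg_d)
    matrix_mc = build_feature_matrix(kept, occ_index,
                                     split.model_construction, split.control_model,
                                     fconfig)
    result = cross_validate(matrix_mc, ga_cfg, k=k,
                            weight_matrix=matrix_fc.restrict_features(kept))
    if not result.consensus_features:
        raise NoModelError("cross-validation produced an empty consensus feature set")
    model = Model(features=result.consensus_features,
                  weights=[fw.w for fw in result.weights],
                  motif_names=[m.name for m in selected],
                  feature_config=fconfig, threshold_fraction=tf,
                  overall_fscore=result.overall_fscore)
    mo = outdir / "model.json"
    model.save(mo)
    done(model=mo)

    # -- stage: validation ---------------------------------------------------
    done = stage("validation")
    val_occ = build_occurrence_index(selected, val_records, threshold_fraction=tf)
    training_ids = (split.model_construction | split.control_model
                    | split.feature_computation | split.control_feature
                    | split.motif_prediction)
    n_top = int(cfg["validation"]["n_top"])
    ranked = rank_genome(model.feature_weights(), val_occ, exclude=training_ids,
                         n_top=n_top, config=fconfig)
    st = outdir / "scores.tsv"
    ranked.to_csv(st, sep="\t", index=False)
    enr = enrichment_of_top(ranked, expressed, n_top=n_top)
    consensus_mask = np.array([f in result.consensus_features for f in matrix_mc.features])
    perm_p = fscore_permutation_pvalue(matrix_mc, consensus_mask,
                                       n_perm=int(cfg["validation"]["n_perm"]), seed=seed)
    fdrs = adjust_fdr([enr.pvalue, perm_p])
    enr.fdr = float(fdrs[0])
    report = {
        "enrichment": enr.to_dict(),
        "fscore_permutation_pvalue": perm_p,
        "fscore_permutation_fdr": float(fdrs[1]),
        "overall_fscore": result.overall_fscore,
        "fold_fscores": result.fold_fscores,
        "n_consensus_features": len(result.consensus_features),
        "significant": bool(fdrs[1] < float(cfg["validation"]["fdr_threshold"])),
    }
    ej = outdir / "enrichment.json"
    ej.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    done(scores=st, enrichment=ej)

    mf = outdir / "manifest.json"
    mf.write_text(json.dumps(manifest.to_dict(), indent=2, sort_keys=True) + "\n")
    return manifest


def reference_recovery_run(seed: int, max_iters: int = 300,
                           threshold_fraction: float = 0.9, k: int = 5) -> dict:
    """Run the core method on the reference simulation and measure recovery.

    Generates the reference cohort (four planted presence features at 0.9/0.1
    penetrance), scans, builds and filters the feature matrix, cross-validates
    the GA, and reports the overall Fscore together with how much of the
    planted architecture the consensus recovered.
    """
    from .synthetic_data import generate_cohort, reference_scenario

    pwms, spec = reference_scenario(seed=seed)
    pos, ctrl, _ = generate_cohort(spec, pwms)
    occ = build_occurrence_index(pwms, pos + ctrl, threshold_fraction=threshold_fraction)
    fconfig = FeatureConfig()
    features = enumerate_candidate_features([p.name for p in pwms], fconfig)
    matrix = build_feature_matrix(features, occ, [p.gene_id for p in pos],
                                  [p.gene_id for p in ctrl], fconfig)
    kept = correlation_filter(matrix, delta=0.0)
    result = cross_validate(matrix.restrict_features(kept),
                            GAConfig(seed=seed, max_iters=max_iters), k=k)
    planted = {str(pf.descriptor) for pf in spec.planted_features}
    consensus = {str(f) for f in result.consensus_features}
    planted_kept = planted & {str(f) for f in kept}
    recovered = planted & consensus
    return {
        "overall_fscore": result.overall_fscore,
        "n_candidate_features": len(features),
        "n_filtered_features": len(kept),
        "planted_surviving_filter": len(planted_kept),
        "n_consensus": len(consensus),
        "recovery": len(recovered) / len(planted),
        "spurious_fraction": (1.0 - len(recovered) / len(consensus)) if consensus else 1.0,
    }


# ---------------------------------------------------------------------------
# Input assembly
# ---------------------------------------------------------------------------

def _synthetic_inputs(cfg: dict, seed: int):
    syn = cfg["synthetic"]
    pwms = [generate_pwm(m["consensus"], float(m.get("sharpness", 0.9)),
                         name=m.get("name")) for m in syn["motifs"]]
    planted = [PlantedFeature(descriptor=FeatureDescriptor.parse(p["feature"]),
                              penetrance_pos=float(p.get("penetrance_pos", 0.9)),
                              penetrance_ctrl=float(p.get("penetrance_ctrl", 0.1)))
               for p in syn["planted"]]
    spec = ArchitectureSpec(planted_features=planted,
                            n_pos=int(syn.get("n_pos", 200)),
                            n_ctrl=int(syn.get("n_ctrl", 200)),
                            background_gc=float(syn.get("gc", 0.40)),
                            seed=seed)
    pos, ctrl, _ = generate_cohort(spec, pwms)
    background = generate_background_regions(int(syn.get("n_background", 50)),
                                             gc=spec.background_gc, seed=seed + 1)
    val_spec = ArchitectureSpec(planted_features=planted,
                                n_pos=int(syn.get("n_validation_pos", 100)),
                                n_ctrl=int(syn.get("n_validation_neg", 100)),
                                background_gc=spec.background_gc, seed=seed + 2)
    vpos, vneg, _ = generate_cohort(val_spec, pwms)
    for r in vpos:
        r.gene_id = "val_" + r.gene_id
    for r in vneg:
        r.gene_id = "val_" + r.gene_id
    expressed = [r.gene_id for r in vpos]
    return pwms, pos, ctrl, background, vpos + vneg, expressed


def _file_inputs(cfg: dict):
    from .promoters import PromoterRecord

    inputs = cfg["inputs"]
    seqs = paio.read_fasta(inputs["promoters_fasta"])
    pos_ids = paio.read_id_list(inputs["positive_list"])
    ctrl_ids = paio.read_id_list(inputs["control_list"])
    missing = [g for g in pos_ids + ctrl_ids if g not in seqs]
    if missing:
        raise DataError(f"gene ids without promoter sequence: {missing[:10]}")

    def rec(g):
        return PromoterRecord(gene_id=g, chrom=g, tss=1500, strand="+", seq=seqs[g])

    pos = [rec(g) for g in pos_ids]
    ctrl = [rec(g) for g in ctrl_ids]
    bg_seqs = paio.read_fasta(inputs["background_fasta"])
    background = [PromoterRecord(gene_id=g, chrom=g, tss=1500, strand="+", seq=s)
                  for g, s in bg_seqs.items()]
    pwms = paio.read_jaspar(inputs["pwms_jaspar"])
    val_ids = [g for g in seqs if g not in set(pos_ids) | set(ctrl_ids)]
    val_records = [rec(g) for g in val_ids]
    expressed = (paio.read_id_list(inputs["expressed_list"])
                 if "expressed_list" in inputs else [])
    return pwms, pos, ctrl, background, val_records, expressed
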