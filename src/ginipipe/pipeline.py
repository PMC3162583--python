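"""End-to-end orchestration of the synthetic-data and analysis stages.

A :class:`RunConfig` (optionally loaded from YAML) selects stages and their
parameters; :func:`run_pipeline` executes them in dependency order inside a
run directory, writing each stage's tables plus a JSON sidecar with the
parameters, the stage seed and input hashes.  Each stage draws its
randomness from a stream derived from the master seed and the stage name,
so adding or re-ordering stages never perturbs another stage's output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import association, famtau, io, nmd, simulate, target_delta

logger = logging.getLogger("ginipipe")

STAGES = ("simulate", "nmd_de", "famtau", "mirdelta", "assoc")


def derive_seed(master_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Serializable configuration for a full pipeline run."""

    seed: int = 0
    stages: tuple = STAGES
    # synthetic design
    n_families: int = 6
    patients_per_family: int = 1
    healthy_per_family: int = 1
    # NMD stage
    n_probes: int = 4000
    n_true_genes: int = 5
    n_stress_genes: int = 10
    effect_log_ratio: float = 1.0
    nmd_noise_sd: float = 0.1
    alpha: float = 0.025
    fc_threshold: float | None = None
    region: tuple = ("Xq27", "Xq28")
    # miRNA stage
    mirna_families: int = 9
    n_mirnas: int = 333
    n_up: int = 3
    n_down: int = 3
    shift: float = 2.0
    family_sd: float = 0.5
    mirna_noise_sd: float = 0.3
    n_permutations: int = 2000
    sign_mode: str = "within-profile"
    # target-delta stage
    flank: int = 25
    top_fraction: float = 0.05
    n_targets: int = 40
    n_seq_mirnas: int = 8
    # association stage
    ci_alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}")
        if "famtau" in self.stages and self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        if "region" in raw:
            raw["region"] = tuple(raw["region"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(d["stages"])
        d["region"] = list(d["region"])
        return d


def run_pipeline(config: RunConfig, outdir) -> dict[str, Path]:
    """Execute the selected stages; returns a map from stage name to output path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(config.to_dict())
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    outputs: dict[str, Path] = {}
    produced: dict[str, object] = {}

    def sidecar(stage, path, extra=None):
        params = {"config_hash": chash, "stage": stage}
        params.update(extra or {})
        io.write_sidecar(path.with_suffix(".json"), params, derive_seed(config.seed, stage))

    try:
        if "simulate" in config.stages:
            stage_seed = derive_seed(config.seed, "simulate")
            design = simulate.StudyDesign(
                n_families=config.n_families,
                patients_per_family=config.patients_per_family,
                healthy_per_family=config.healthy_per_family,
                seed=stage_seed,
            )
            nmd_cfg = simulate.NmdSimConfig(
                n_probes=config.n_probes,
                n_true_genes=config.n_true_genes,
                n_stress_genes=config.n_stress_genes,
                effect_log_ratio=config.effect_log_ratio,
                noise_sd=config.nmd_noise_sd,
            )
            samples, nmd_truth = simulate.simulate_nmd_arrays(design, nmd_cfg)
            arr_dir = outdir / "arrays"
            for s in samples:
                io.write_array_sample(
                    s, arr_dir / f"{s.sample_id}.tsv", meta={"config_hash": chash}
                )
            io.write_sample_sheet(
                design.sample_sheet(), outdir / "samples.tsv", meta={"config_hash": chash}
            )
            io.write_tsv(nmd_truth, outdir / "nmd_truth.tsv", meta={"config_hash": chash})

            mirna_design = simulate.StudyDesign(
                n_families=config.mirna_families, seed=derive_seed(config.seed, "simulate-mirna")
            )
            mirna_cfg = simulate.MirnaSimConfig(
                n_mirnas=config.n_mirnas,
                n_up=config.n_up,
                n_down=config.n_down,
                shift=config.shift,
                family_sd=config.family_sd,
                noise_sd=config.mirna_noise_sd,
            )
            expr, mirna_truth = simulate.simulate_mirna_matrix(mirna_design, mirna_cfg)
            io.write_expression_matrix(
                expr.values, outdir / "mirna_matrix.tsv", meta={"config_hash": chash}
            )
            io.write_sample_sheet(
                mirna_design.sample_sheet(),
                outdir / "mirna_samples.tsv",
                meta={"config_hash": chash},
            )
            io.write_tsv(mirna_truth, outdir / "mirna_truth.tsv", meta={"config_hash": chash})

            seq_cfg = simulate.SequenceSimConfig(
                n_targets=config.n_targets,
                n_mirnas=config.n_seq_mirnas,
                n_planted_sites=min(20, max(1, config.n_targets // 2)),
            )
            mirnas, targets, variants, seq_truth = simulate.simulate_sequences_and_variants(
                seq_cfg, seed=derive_seed(config.seed, "simulate-seq")
            )
            io.write_fasta(mirnas, outdir / "mirnas.fa")
            io.write_fasta(targets, outdir / "targets.fa")
            io.write_variant_table(variants, outdir / "variants.tsv", meta={"config_hash": chash})
            io.write_tsv(seq_truth, outdir / "seq_truth.tsv", meta={"config_hash": chash})

            counts = pd.DataFrame(
                [
                    {"group": "cases", "carriers": t.case_carriers,
                     "total": t.case_carriers + t.case_noncarriers, "role": "case"}
                    for t in [simulate.simulate_genotype_tables(
                        simulate.AssocSimConfig(), seed=derive_seed(config.seed, "simulate-assoc")
                    )[0]]
                ]
                + [
                    {"group": "controls", "carriers": t.control_carriers,
                     "total": t.control_carriers + t.control_noncarriers, "role": "control"}
                    for t in [simulate.simulate_genotype_tables(
                        simulate.AssocSimConfig(), seed=derive_seed(config.seed, "simulate-assoc")
                    )[0]]
                ]
            )
            io.write_counts_table(counts, outdir / "counts.tsv", meta={"config_hash": chash})
            sidecar("simulate", outdir / "samples.tsv")
            outputs["simulate"] = outdir
            produced["samples"] = samples
            produced["expr"] = expr
            produced["mirnas"] = mirnas
            produced["targets"] = targets
            produced["variants"] = variants
            produced["counts"] = counts

        if "nmd_de" in config.stages:
            samples = produced["samples"]
            calls = nmd.run_nmd_de(
                samples,
                band_whitelist=config.region,
                alpha=config.alpha,
                fc_threshold=config.fc_threshold,
            )
            path = outdir / "de.tsv"
            io.write_tsv(calls.reset_index(), path, meta={"config_hash": chash})
            sidecar("nmd_de", path, {"alpha": config.alpha})
            logger.info("nmd_de: %d probes fitted, %d selected", len(calls), calls["selected"].sum())
            outputs["nmd_de"] = path

        if "famtau" in config.stages:
            expr = produced["expr"]
            meta = expr.sample_meta.copy()
            meta["is_patient"] = meta["status"] == "affected"
            profiles = famtau.RankedProfileSet(values=expr.values, sample_meta=meta)
            perm = famtau.permutation_pvalues(
                profiles,
                n_permutations=config.n_permutations,
                seed=derive_seed(config.seed, "famtau"),
                sign_mode=config.sign_mode,
            )
            report = perm.report()
            path = outdir / "famtau.tsv"
            io.write_tsv(report.reset_index(names="mirna_id"), path, meta={"config_hash": chash})
            tree = famtau.ward_cluster(famtau.pairwise_distance_matrix(profiles))
            io.write_newick(tree.to_newick(), outdir / "famtau_dendrogram.nwk")
            sidecar("famtau", path, {"B": config.n_permutations})
            outputs["famtau"] = path

        if "mirdelta" in config.stages:
            deltas = target_delta.delta_scores(
                produced["mirnas"], produced["targets"], produced["variants"],
                flank=config.flank,
            )
            flagged = target_delta.select_top_fraction(deltas, config.top_fraction)
            path = outdir / "deltas.tsv"
            io.write_tsv(flagged, path, meta={"config_hash": chash})
            sidecar("mirdelta", path, {"flank": config.flank, "top": config.top_fraction})
            outputs["mirdelta"] = path

        if "assoc" in config.stages:
            counts = produced["counts"]
            cases = counts[counts["role"] == "case"]
            controls = counts[counts["role"] == "control"]
            pooled = association.pool_controls(
                list(zip(controls["carriers"], controls["total"]))
            )
            rows = []
            for _, r in cases.iterrows():
                table = association.ContingencyTable2x2(
                    case_carriers=int(r["carriers"]),
                    case_noncarriers=int(r["total"] - r["carriers"]),
                    control_carriers=pooled[0],
                    control_noncarriers=pooled[1] - pooled[0],
                    case_label=str(r["group"]),
                )
                res = association.odds_ratio_woolf(table, alpha=config.ci_alpha)
                freq = association.carrier_frequency(int(r["carriers"]), int(r["total"]))
                rows.append(
                    {
                        "group": r["group"],
                        "carrier_frequency": freq.formatted(),
                        "odds_ratio": res.odds_ratio,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                    }
                )
            path = outdir / "assoc.tsv"
            io.write_tsv(pd.DataFrame(rows), path, meta={"config_hash": chash})
            sidecar("assoc", path)
            outputs["assoc"] = path
    except Exception as err:
        stage = next((s for s in STAGES if s not in outputs and s in config.stages), "?")
        raise RuntimeError(f"pipeline failed in stage {stage!r}: {err}") from err
    return outputs
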