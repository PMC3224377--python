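"""End-to-end pipeline: simulate/load inputs, coverage, cut-site
enrichment, low-coverage regions, bias-corrected nucleosome calls,
physical-descriptor profiles, energy-based predictions and metagene
aggregation, with a manifest recording every applied parameter.

Outputs are deterministic for a given configuration (no timestamps), so a
rerun reproduces the run directory bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import fields
from pathlib import Path

import numpy as np

from . import __version__, aggregate, io, mnase, physics, regions, synth
from .errors import ConfigError

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "coverage": {"cap_k": 5.0, "extend_to": 147},
    "cutsites": {"end": "5p"},
    "lr": {"q": 0.05, "min_len": 50, "merge_gap": 20},
    "clr": {"min_len": 50},
    "correct": {"alpha": 0.5, "mode": "log2"},
    "smooth": {"keep_fraction": 0.02},
    "call": {"height_threshold_quantile": 0.25},
    "classify": {"overlap_max": 50, "h_min": 0.4, "contrast_min": 0.2},
    "ktotal": {"smooth_window": 1},
    "energy": {"stride": 1},
    "predict": {"depleted_quantile": 0.9, "enriched_quantile": 0.1, "min_len": 50},
    "metagene": {"flank": 1000},
}

ALL_STAGES = ("coverage", "cutsites", "regions", "nucleosomes", "physics", "metagene")


def _merged_params(config: dict) -> dict:
    params = {k: dict(v) for k, v in DEFAULT_PARAMS.items()}
    for stage, overrides in (config.get("params") or {}).items():
        if stage not in params:
            raise ConfigError(f"unknown parameter group {stage!r}")
        params[stage].update(overrides)
    return params


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: dict, outdir) -> dict:
    """Run the configured stages; returns (and writes) the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = _merged_params(config)
    stages = tuple(config.get("stages") or ALL_STAGES)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}")
    seed = int(config.get("seed", 0))
    manifest: dict = {
        "nucleoflex_version": __version__,
        "seed": seed,
        "stages": list(stages),
        "parameters": params,
        "inputs": {},
        "outputs": [],
    }

    def emit(name):
        manifest["outputs"].append(name)
        return outdir / name

    truth = None
    stage_name = "inputs"
    try:
        if config.get("simulate") is not None:
            sim_opts = dict(config.get("simulate") or {})
            sim_opts.setdefault("seed", seed)
            valid = {f.name for f in fields(synth.SimConfig)}
            bad = set(sim_opts) - valid
            if bad:
                raise ConfigError(f"unknown simulate options {sorted(bad)}")
            sim = synth.SimConfig(**sim_opts)
            genome, truth = synth.generate_genome(sim)
            truth = synth.place_nucleosomes(genome, truth, sim)
            naked_reads, naked_counts = synth.simulate_digestion(genome, sim, None, stage=2)
            nuc_reads, nuc_counts = synth.simulate_digestion(genome, sim, truth.dyads, stage=3)
            truth.end_pair_counts = {"naked": naked_counts, "nucleosomal": nuc_counts}
            io.write_fasta(genome, emit("genome.fa"))
            io.write_gff3(truth.genes, emit("annotation.gff3"))
            io.write_bed(naked_reads, emit("reads_naked.bed"))
            io.write_bed(nuc_reads, emit("reads_nucleosomal.bed"))
            io.write_bed(truth.ndrs, emit("truth_ndrs.bed"))
            with open(emit("truth_dyads.tsv"), "w") as fh:
                fh.write("chrom\tdyad\tclass\n")
                for d in truth.dyads:
                    fh.write(f"{d.chrom}\t{d.pos}\t{d.cls}\n")
            genes = truth.genes
        else:
            inputs = config.get("inputs") or {}
            for key in ("genome", "reads_nucleosomal", "reads_naked"):
                if key not in inputs:
                    raise ConfigError(f"config inputs.{key} is required without simulate")
            genome = io.read_fasta(inputs["genome"])
            genes = io.read_gff3_genes(inputs["annotation"]) if "annotation" in inputs else []
            naked_reads = mnase.read_alignments(inputs["reads_naked"])
            nuc_reads = mnase.read_alignments(inputs["reads_nucleosomal"])
            for key, path in inputs.items():
                manifest["inputs"][key] = _sha256(Path(path))

        lengths = {c: len(s) for c, s in genome.items()}

        stage_name = "coverage"
        cap_k = params["coverage"]["cap_k"]
        extend_to = params["coverage"]["extend_to"]
        naked_reads = mnase.cap_duplicates(naked_reads, k=cap_k)
        nuc_reads = mnase.cap_duplicates(nuc_reads, k=cap_k)

        def _coverage(reads):
            frags = (mnase.extend_reads(reads, length=extend_to, genome_lengths=lengths)
                     if extend_to else reads)
            return mnase.rpm_normalize(mnase.build_coverage(frags, lengths))

        naked_cov = _coverage(naked_reads)
        nuc_cov = _coverage(nuc_reads)
        if "coverage" in stages:
            io.write_bedgraph(naked_cov, emit("coverage_naked.bedgraph"),
                              header={"sample": "naked", "units": "rpm"})
            io.write_bedgraph(nuc_cov, emit("coverage_nucleosomal.bedgraph"),
                              header={"sample": "nucleosomal", "units": "rpm"})

        if "cutsites" in stages:
            stage_name = "cutsites"
            background = mnase.genome_background(genome)
            for label, reads in (("naked", naked_reads), ("nucleosomal", nuc_reads)):
                counts, n_sites, _ = mnase.extract_cut_tetramers(
                    reads, genome, end=params["cutsites"]["end"])
                stats = mnase.tetramer_enrichment(counts, n_sites, background)
                stats.to_csv(emit(f"enrichment_{label}.tsv"), sep="\t", index=False)
                if label == "naked":
                    naked_enrichment = stats

        lr_naked = lr_nuc = None
        if "regions" in stages:
            stage_name = "regions"
            lr_naked = regions.detect_lr(naked_cov, kind="LR_naked", **params["lr"])
            lr_nuc = regions.detect_lr(nuc_cov, kind="LR_nuc", **params["lr"])
            clrs = regions.common_lr(lr_naked, lr_nuc, **params["clr"])
            io.write_bed(lr_naked, emit("lr_naked.bed"))
            io.write_bed(lr_nuc, emit("lr_nucleosomal.bed"))
            io.write_bed(clrs, emit("clr.bed"))

        calls = None
        if "nucleosomes" in stages:
            stage_name = "nucleosomes"
            corrected = regions.correct_bias(nuc_cov, naked_cov, **params["correct"])
            smoothed = regions.fft_smooth(corrected, **params["smooth"])
            calls = regions.classify_calls(
                regions.call_nucleosomes(smoothed, **params["call"]),
                smoothed=smoothed, **params["classify"])
            io.write_bedgraph(corrected, emit("corrected.bedgraph"),
                              header=params["correct"])
            io.write_bed(calls, emit("nucleosome_calls.bed"))

        energy = None
        if "physics" in stages:
            stage_name = "physics"
            table = (physics.StiffnessTable.from_tsv(config["inputs"]["stiffness_table"])
                     if (config.get("inputs") or {}).get("stiffness_table")
                     else physics.load_dinucleotide_table())
            shape = (physics.NucleosomeShape.from_tsv(config["inputs"]["shape_table"])
                     if (config.get("inputs") or {}).get("shape_table")
                     else physics.NucleosomeShape.ideal())
            ktot = {c: physics.ktotal_profile(s, table, **params["ktotal"])
                    for c, s in genome.items()}
            energy = physics.energy_profile(genome, table, shape,
                                            stride=params["energy"]["stride"])
            depleted, enriched = physics.predict_regions(energy, **params["predict"])
            io.write_bedgraph(ktot, emit("ktotal.bedgraph"))
            io.write_bedgraph(energy, emit("energy.bedgraph"))
            io.write_bed(depleted + enriched, emit("predicted_regions.bed"))

        if "metagene" in stages and genes:
            stage_name = "metagene"
            flank = params["metagene"]["flank"]
            for which in ("tss", "tts"):
                anchors = aggregate.tss_tts_anchors(genes, which=which)
                for label, track in (("naked", naked_cov), ("nucleosomal", nuc_cov)):
                    mean, n = aggregate.anchor_profile(track, anchors, flank=flank)
                    io.write_profile_tsv(mean, n, emit(f"metagene_{which}_{label}.tsv"),
                                         flank=flank)
                if energy is not None:
                    mean, n = aggregate.anchor_profile(energy, anchors, flank=flank)
                    io.write_profile_tsv(mean, n, emit(f"metagene_{which}_energy.tsv"),
                                         flank=flank)

        if truth is not None and calls is not None:
            report = synth.truth_report(
                truth, calls=calls, lrs=lr_naked,
                enrichment=naked_enrichment if "cutsites" in stages else None)
            report.to_csv(emit("truth_report.tsv"), sep="\t", index=False)
    except Exception as exc:
        raise ConfigError(f"pipeline stage {stage_name!r} failed: {exc}") from exc

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
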