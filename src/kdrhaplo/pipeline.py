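"""End-to-end orchestration: simulate -> call -> annotate -> network ->
clades -> phase -> trends, with all outputs written to one bundle directory.

Every source of randomness flows from the single config seed; per-pool
simulation seeds are derived from it with a SeedSequence spawn, so the whole
bundle is byte-reproducible for a fixed configuration.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as kio
from .annotate import annotate_table, trim_primers
from .caller import (CallerParams, call_haplotypes, demultiplex, filter_reads,
                     merge_tables, validate_frequency_table)
from .clades import classify
from .network import build_network, connection_limit, export_network
from .phasing import (TwoSegmentPopulation, infer_min_origins, is_phaseable,
                      phase_population)
from .refpanel import (SEGMENTS, ErrorModel, build_default_panel,
                       demo_populations, panel_index, simulate_pool,
                       write_manifest)
from .trends import trajectories, trajectory_table

log = logging.getLogger(__name__)

DEFAULT_MUTATIONS = ("F1534C", "V1016I", "V1016G", "I1011M", "S989P", "T1520I")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    fastq: str | None = None          # existing reads; None -> simulate demo
    manifest: str | None = None
    reads_per_segment: int = 2000
    caller: CallerParams = field(default_factory=CallerParams)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    network_confidence: float = 0.95
    mutations: tuple[str, ...] = DEFAULT_MUTATIONS
    monomorphism_threshold: float = 1.0
    trend_country: str = "Brazil"

    def validate(self) -> None:
        for p in (self.fastq, self.manifest):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")
        if self.fastq is not None and self.manifest is None:
            raise ValueError("a manifest is required when fastq is given")


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic child seeds (< 2**31) from the master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the output-bundle manifest dict.

    On a stage failure, partial outputs are kept and the bundle manifest
    records the failed stage before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"seed": config.seed, "stage": None, "outputs": {},
                    "parameters": {
                        "caller": asdict(config.caller),
                        "error_model": asdict(config.error_model),
                        "network_confidence": config.network_confidence,
                        "monomorphism_threshold": config.monomorphism_threshold,
                    },
                    "versions": {"python": sys.version.split()[0]}}

    def record(key: str, path: Path):
        bundle["outputs"][key] = str(path)

    def fail(stage: str, exc: Exception):
        bundle["stage"] = f"failed:{stage}"
        (out / "bundle.json").write_text(json.dumps(bundle, indent=2))
        raise exc

    models, panel = build_default_panel()
    for seg in SEGMENTS:
        kio.write_segment_json(models[seg], out / f"segment_{seg}.json")
        record(f"segment_{seg}", out / f"segment_{seg}.json")
    kio.write_fasta({h.name: h.sequence for h in panel}, out / "panel.fasta")
    record("panel", out / "panel.fasta")

    # --- reads -----------------------------------------------------------
    try:
        if config.fastq is None:
            configs = demo_populations(config.reads_per_segment)
            write_manifest(configs, out / "manifest.tsv")
            record("manifest", out / "manifest.tsv")
            reads = []
            for cfg, s in zip(configs, derive_seeds(config.seed, len(configs))):
                reads.extend(simulate_pool(cfg, panel, config.error_model, s))
            kio.write_fastq(reads, out / "reads.fastq")
            record("reads", out / "reads.fastq")
            manifest = kio.read_table(out / "manifest.tsv")
            manifest["barcode"] = manifest["barcode"].astype(str)
        else:
            reads = kio.read_fastq(config.fastq)
            manifest = kio.read_table(config.manifest)
            manifest["barcode"] = manifest["barcode"].astype(str)
    except Exception as exc:  # noqa: BLE001
        fail("simulate", exc)

    # --- call ------------------------------------------------------------
    try:
        assigned, unassigned = demultiplex(reads, manifest, config.caller)
        log.info("demultiplexed %d reads (%d unassigned)",
                 len(reads), len(unassigned))
        calls_by_pop: dict[str, list] = {}
        for pop, pop_reads in assigned.items():
            for seg in SEGMENTS:
                retained = filter_reads(pop_reads, models[seg], config.caller)
                calls = call_haplotypes(retained, config.caller,
                                        population_id=pop, segment_id=seg)
                if calls:
                    calls_by_pop.setdefault(pop, []).extend(calls)
        name_map = {trim_primers(h.sequence, models[h.segment_id]): h.name
                    for h in panel}
        table, name_to_seq = merge_tables(calls_by_pop, manifest, name_map)
        validate_frequency_table(table)
        kio.write_table(table, out / "frequency_table.tsv")
        kio.write_fasta(name_to_seq, out / "haplotypes.fasta")
        record("frequency_table", out / "frequency_table.tsv")
        record("haplotypes", out / "haplotypes.fasta")
    except Exception as exc:  # noqa: BLE001
        fail("call", exc)

    # --- annotate --------------------------------------------------------
    try:
        annotated, summary, annotations = annotate_table(table, name_to_seq, models)
        kio.write_table(annotated, out / "annotated_table.tsv")
        kio.write_table(summary, out / "population_summary.tsv")
        record("annotated_table", out / "annotated_table.tsv")
        record("population_summary", out / "population_summary.tsv")
    except Exception as exc:  # noqa: BLE001
        fail("annotate", exc)

    # --- networks --------------------------------------------------------
    try:
        for seg in SEGMENTS:
            seg_rows = annotated[annotated["segment_id"] == seg]
            seqs = {n: name_to_seq[n] for n in seg_rows["haplotype_name"].unique()}
            freqs = seg_rows.groupby("haplotype_name")["frequency"].sum().to_dict()
            labels = {n: annotations[n].label for n in seqs}
            net = build_network(seqs, freqs, labels,
                                confidence=config.network_confidence)
            export_network(net, out / f"network_{seg}.graphml")
            record(f"network_{seg}", out / f"network_{seg}.graphml")
    except Exception as exc:  # noqa: BLE001
        fail("network", exc)

    # --- clades ----------------------------------------------------------
    try:
        iis6_names = sorted(annotated.loc[annotated["segment_id"] == "IIS6",
                                          "haplotype_name"].unique())
        assignment = classify({n: name_to_seq[n] for n in iis6_names},
                              models["IIS6"])
        clades_df = pd.DataFrame(sorted(assignment.labels.items()),
                                 columns=["haplotype_name", "clade"])
        kio.write_table(clades_df, out / "clades.tsv")
        record("clades", out / "clades.tsv")
    except Exception as exc:  # noqa: BLE001
        fail("clades", exc)

    # --- phasing / origins ----------------------------------------------
    try:
        pops = []
        for pop, g in annotated.groupby("population_id"):
            iis6 = g[g["segment_id"] == "IIS6"]
            iiis6 = g[g["segment_id"] == "IIIS6"]
            if iis6.empty or iiis6.empty:
                continue
            pops.append(TwoSegmentPopulation(
                pop,
                dict(zip(iis6["haplotype_name"], iis6["frequency"])),
                dict(zip(iiis6["haplotype_name"], iiis6["frequency"])),
                country=g["country"].iloc[0], continent=g["continent"].iloc[0],
                year=int(g["year"].iloc[0])))
        phased = []
        for pop in pops:
            if is_phaseable(pop, config.monomorphism_threshold):
                phased.extend(phase_population(pop, assignment,
                                               config.monomorphism_threshold))
        phased_df = pd.DataFrame(
            [[p.name, p.population_id, p.iis6_name, p.iis6_clade,
              p.iiis6_name, p.frequency] for p in phased],
            columns=["phased_name", "population_id", "iis6_name",
                     "iis6_clade", "iiis6_name", "frequency"])
        kio.write_table(phased_df, out / "phased.tsv")
        record("phased", out / "phased.tsv")

        origins = {}
        for mut in config.mutations:
            rep = infer_min_origins(phased, mut, annotations)
            origins[mut] = {
                "min_origins": rep.min_origins,
                "unobserved": rep.unobserved,
                "backgrounds": sorted(list(b) for b in rep.backgrounds),
                "supporting_populations": rep.supporting_populations,
            }
        (out / "origins.json").write_text(json.dumps(origins, indent=2))
        record("origins", out / "origins.json")
    except Exception as exc:  # noqa: BLE001
        fail("phase", exc)

    # --- trends ----------------------------------------------------------
    try:
        country = config.trend_country
        if annotated.loc[annotated["country"] == country, "year"].nunique() >= 2:
            trajs = trajectories(annotated, country)
            kio.write_table(trajectory_table(trajs),
                            out / f"trends_{country}.tsv")
            record("trends", out / f"trends_{country}.tsv")
        else:
            log.info("skipping trends: fewer than 2 years for %s", country)
    except Exception as exc:  # noqa: BLE001
        fail("trends", exc)

    bundle["stage"] = "complete"
    (out / "bundle.json").write_text(json.dumps(bundle, indent=2))
    return bundle
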