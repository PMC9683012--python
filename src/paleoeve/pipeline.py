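"""End-to-end orchestration: simulate -> search/synteny -> date -> neutrality -> report.

The run emulates the full paleovirological study on synthetic data with known
truth: two independent loci (each an EVE insertion on the same host branch)
are generated, presence is called per taxon by the synteny screen and by the
alignment-coverage method, the two orthologue clades are merged into one
calibrated dating analysis (paralogue root), and the EVE region is tested for
neutral evolution against resampled noncoding nulls.  All stage seeds derive
from one global seed; outputs are plain-text artifacts in standard formats.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import alnkit, clockdate, neutrality, synteny, synthsim

log = logging.getLogger("paleoeve")


@dataclass
class DatingConfig:
    root_age: float = 200.0            # paralogue-root starting age, My
    calibration_sd_fraction: float = 0.03
    calibration_sd_min: float = 1.0
    chain_length: int = 60_000
    sample_every: int = 30
    burnin_fraction: float = 0.25
    clock_kind: str = "strict"
    estimate_model: bool = False
    gamma_shape: float = 1.0
    trim_gap_fraction: float = 0.8


@dataclass
class NeutralityConfig:
    n_null: int = 100
    alternative: str = "less"


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "paleoeve_run"
    loci: tuple[str, ...] = ("locusA", "locusB")
    stages: tuple[str, ...] = ("simulate", "synteny", "date", "neutral", "report")
    simulation: synthsim.SimulationConfig = field(default_factory=synthsim.SimulationConfig)
    dating: DatingConfig = field(default_factory=DatingConfig)
    neutrality: NeutralityConfig = field(default_factory=NeutralityConfig)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = synthsim.SimulationConfig(**raw.pop("simulation", {}))
        dating = DatingConfig(**raw.pop("dating", {}))
        neut = NeutralityConfig(**raw.pop("neutrality", {}))
        for key in ("loci", "stages"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(simulation=sim, dating=dating, neutrality=neut, **raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


@dataclass
class StageReport:
    stage: str
    inputs_digest: str
    outputs: list[str]
    warnings: list[str] = field(default_factory=list)


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2^31, derived by hashing the stage name."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31 - 1)


class PipelineError(RuntimeError):
    pass


class PipelineRun:
    """Holds in-memory artifacts while stages execute in dependency order."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.out_dir)
        self.datasets: dict[str, synthsim.SimulatedDataset] = {}
        self.matrix: synteny.PresenceMatrix | None = None
        self.dating_summary: dict | None = None
        self.min_ages: dict[str, clockdate.MinAgeResult] = {}
        self.ks_results: dict[str, neutrality.KSResult] = {}
        self.reports: list[StageReport] = []
        self._digest = hashlib.sha256(
            json.dumps(dataclasses.asdict(config), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    # -- stages ------------------------------------------------------------
    def simulate(self) -> StageReport:
        outputs = []
        sim_dir = self.out / "simulate"
        sim_dir.mkdir(parents=True, exist_ok=True)
        tree = synthsim.default_host_tree()
        for locus in self.config.loci:
            seed = stage_seed(self.config.seed, f"simulate:{locus}")
            cfg = dataclasses.replace(self.config.simulation, seed=seed)
            ds = synthsim.simulate_dataset(cfg, tree=tree)
            self.datasets[locus] = ds
            fasta = sim_dir / f"{locus}.fasta"
            with open(fasta, "w") as fh:
                for taxon in ds.tree.taxa:
                    fh.write(f">{taxon}\n{ds.sequence(taxon)}\n")
            bed = sim_dir / f"{locus}.features.bed"
            with open(bed, "w") as fh:
                for feat in ds.ancestral.features:
                    fh.write(f"ancestral\t{feat.start}\t{feat.end}\t{feat.name}\t0\t"
                             f"{'+' if feat.strand > 0 else '-'}\n")
            truth = sim_dir / f"{locus}.truth.tsv"
            pd.DataFrame(
                [{"taxon": t, "present": ds.truth.presence[t],
                  "lost": t in ds.truth.lost} for t in ds.tree.taxa]
            ).to_csv(truth, sep="\t", index=False)
            outputs += [str(fasta), str(bed), str(truth)]
        self.config.to_yaml(sim_dir / "config.yaml")
        outputs.append(str(sim_dir / "config.yaml"))
        return StageReport("simulate", self._digest, outputs)

    def synteny_stage(self) -> StageReport:
        if not self.datasets:
            raise PipelineError("synteny requires the simulate stage")
        out_dir = self.out / "synteny"
        out_dir.mkdir(parents=True, exist_ok=True)
        calls = []
        hit_rows = []
        for locus, ds in self.datasets.items():
            landmarks = synteny.LandmarkSet(
                tuple(ds.ancestral.upstream_landmarks),
                tuple(ds.ancestral.downstream_landmarks),
                ds.ancestral.landmark_proteins)
            for taxon in ds.tree.taxa:
                call = synteny.screen_taxon(
                    taxon, ds.sequence(taxon), landmarks,
                    ds.ancestral.core_proteins, locus=locus,
                    template=ds.ancestral.template)
                calls.append(call)
                for group in call.hit_groups:
                    from .seqsearch import annotate_inactivation

                    ann = annotate_inactivation(group)
                    hit_rows.append({
                        "locus": locus, "taxon": taxon, "probe": group.probe_name,
                        "start": group.subject_start + 1,      # 1-based report
                        "end": group.subject_end,
                        "strand": "+" if group.strand > 0 else "-",
                        "evalue": group.significance,
                        "query_cover_pct": round(group.query_cover_pct, 2),
                        "n_stops": len(ann.stop_positions),
                        "n_frameshifts": len(ann.frameshift_positions),
                    })
            # independent method: coverage in the (true) alignment slice
            aln = ds.true_alignment()
            calls.extend(synteny.presence_from_alignment(
                aln, ds.ancestral.eve_interval, locus=locus))
        self.matrix = synteny.build_presence_matrix(calls)
        matrix_path = out_dir / "presence_matrix.tsv"
        self.matrix.to_dataframe().to_csv(matrix_path, sep="\t", index=False)
        hits_path = out_dir / "region_hits.tsv"
        pd.DataFrame(hit_rows).to_csv(hits_path, sep="\t", index=False)
        return StageReport("synteny", self._digest, [str(matrix_path), str(hits_path)])

    def date_stage(self) -> StageReport:
        if self.matrix is None:
            raise PipelineError("dating requires the synteny stage")
        cfgd = self.config.dating
        out_dir = self.out / "date"
        out_dir.mkdir(parents=True, exist_ok=True)
        host = next(iter(self.datasets.values())).tree

        carriers = {}
        for locus in self.config.loci:
            presence = self.matrix.presence_dict(locus, method="hit")
            self.min_ages[locus] = clockdate.min_age_from_presence(host, presence, locus)
            carriers[locus] = self.min_ages[locus].carriers

        locus_a, locus_b = self.config.loci[:2]
        sub_alns = {}
        for locus in (locus_a, locus_b):
            ds = self.datasets[locus]
            polb = ds.ancestral.feature("POLB")
            aln = ds.true_alignment(taxa=carriers[locus], columns=(polb.start, polb.end))
            label = "A" if locus == locus_a else "B"
            sub_alns[locus] = alnkit.MultipleAlignment(
                [f"{t}__{label}" for t in aln.ids], aln.rows)
        merged = alnkit.merge_alignments(sub_alns[locus_a], sub_alns[locus_b])
        merged = alnkit.trim_columns(merged, cfgd.trim_gap_fraction)
        aln_path = out_dir / "merged_polb.fasta"
        merged.write_fasta(str(aln_path))

        topo = clockdate.paralogue_join(host, carriers[locus_a], carriers[locus_b],
                                        cfgd.root_age)
        calibrations = []
        for locus, label in ((locus_a, "A"), (locus_b, "B")):
            sub = clockdate.HostTree.from_newick(host.restricted_newick(carriers[locus]))
            for node in sub.root.postorder():
                if not node.is_leaf:
                    taxa = tuple(f"{t}__{label}" for t in node.tip_labels())
                    sd = max(cfgd.calibration_sd_min,
                             cfgd.calibration_sd_fraction * node.age)
                    calibrations.append(clockdate.CalibrationPrior(taxa, node.age, sd))
        from .models import GTRModel

        model = GTRModel(gamma_shape=cfgd.gamma_shape)
        clock = clockdate.ClockModel(kind=cfgd.clock_kind,
                                     rate=self.config.simulation.clock_rate)
        mcfg = clockdate.MCMCConfig(
            chain_length=cfgd.chain_length, sample_every=cfgd.sample_every,
            burnin_fraction=cfgd.burnin_fraction,
            seed=stage_seed(self.config.seed, "date"),
            estimate_model=cfgd.estimate_model)
        trace = clockdate.mcmc_run(merged, topo, calibrations, clock, model, mcfg)
        trace_path = out_dir / "trace.tsv"
        with open(trace_path, "w") as fh:
            trace.to_tsv(fh)
        summaries = clockdate.summarize_trace(trace)

        rows = []
        clade_a = frozenset(f"{t}__A" for t in carriers[locus_a])
        clade_b = frozenset(f"{t}__B" for t in carriers[locus_b])
        names = {"root_age": "root (paralogue MRCA)"}
        for name, summ in summaries.items():
            if summ.clade == clade_a:
                names[name] = f"{locus_a} MRCA"
            elif summ.clade == clade_b:
                names[name] = f"{locus_b} MRCA"
        for name, label in names.items():
            s = summaries[name]
            rows.append({"node": label, "mean": round(s.mean, 2),
                         "median": round(s.median, 2),
                         "hpd95_low": round(s.hpd_low, 2),
                         "hpd95_high": round(s.hpd_high, 2),
                         "ess": round(s.ess, 1)})
        s = summaries["clock_rate"]
        rows.append({"node": "clock rate (subs/site/My)", "mean": round(s.mean, 6),
                     "median": round(s.median, 6), "hpd95_low": round(s.hpd_low, 6),
                     "hpd95_high": round(s.hpd_high, 6), "ess": round(s.ess, 1)})
        self.dating_summary = {
            "rows": rows, "summaries": summaries,
            "names": names,
            "min_ages": {l: r.min_age for l, r in self.min_ages.items()},
        }
        summary_path = out_dir / "dating_summary.tsv"
        pd.DataFrame(rows).to_csv(summary_path, sep="\t", index=False)
        low_ess = [n for n, s2 in summaries.items() if s2.ess < 200]
        warnings = ([f"ESS below 200 for: {', '.join(sorted(low_ess))}"]
                    if low_ess else [])
        return StageReport("date", self._digest,
                           [str(aln_path), str(trace_path), str(summary_path)], warnings)

    def neutral_stage(self) -> StageReport:
        if not self.datasets:
            raise PipelineError("neutrality requires the simulate stage")
        cfgn = self.config.neutrality
        out_dir = self.out / "neutral"
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for locus, ds in self.datasets.items():
            # distances are taken between the taxa that carry the element
            # (outgroups have no sequence at the EVE columns at all)
            if self.matrix is not None:
                presence = self.matrix.presence_dict(locus, method="hit")
                carriers = [t for t, s in presence.items() if s == synteny.PRESENT]
            else:
                carriers = [t for t, p in ds.truth.presence.items() if p]
            if len(carriers) < 3:
                raise PipelineError(f"too few carriers for neutrality test of {locus}")
            aln = ds.true_alignment(taxa=sorted(carriers))
            eve = ds.ancestral.eve_interval
            length = eve[1] - eve[0]
            seed = stage_seed(self.config.seed, f"neutral:{locus}")
            # nulls of exactly the EVE length come from a simulated neutral
            # noncoding neighbourhood (the broad surroundings of the locus);
            # disjoint windows keep the region-rank permutation exchangeable
            neighborhood = synthsim.simulate_neighborhood(
                ds.tree,
                dataclasses.replace(self.config.simulation, indel_rate_factor=0.0),
                cfgn.n_null * length, seed)
            keep = [i for i, t in enumerate(neighborhood.ids) if t in set(carriers)]
            neighborhood = alnkit.MultipleAlignment(
                [neighborhood.ids[i] for i in keep],
                [neighborhood.rows[i] for i in keep])
            nulls = [(i * length, (i + 1) * length) for i in range(cfgn.n_null)]
            focal = neutrality.region_distances(aln, eve)
            by_region = [neutrality.region_distances(neighborhood, r) for r in nulls]
            ks = neutrality.ks_region_rank_test(focal, by_region, cfgn.alternative)
            self.ks_results[locus] = ks
            rows.append({"locus": locus, "D": round(ks.statistic, 4),
                         "p": round(ks.pvalue, 4), "alternative": ks.alternative,
                         "method": ks.method, "n_null_regions": len(nulls),
                         "null_length": length})
        ks_path = out_dir / "ks_report.tsv"
        pd.DataFrame(rows).to_csv(ks_path, sep="\t", index=False)
        return StageReport("neutral", self._digest, [str(ks_path)])

    def report_stage(self) -> StageReport:
        out_dir = self.out
        lines = ["# Run report", ""]
        lines.append("## Presence matrix")
        if self.matrix is not None:
            df = self.matrix.to_dataframe()
            lines.append(df.to_string(index=False))
            comp = synteny.compare_methods(self.matrix)
            lines.append(f"\nmethod agreement: {comp.agreement:.2%} "
                         f"({len(comp.discordant)} discordant cells)")
        else:
            lines.append("(synteny stage not run)")
        lines.append("\n## Dating summary")
        if self.dating_summary is not None:
            lines.append(pd.DataFrame(self.dating_summary["rows"]).to_string(index=False))
            for locus, age in self.dating_summary["min_ages"].items():
                lines.append(f"minimum age ({locus}, carrier MRCA): {age:.1f} My")
        else:
            lines.append("(dating stage not run)")
        lines.append("\n## Neutrality")
        if self.ks_results:
            for locus, ks in self.ks_results.items():
                lines.append(f"{locus}: D={ks.statistic:.3f} one-tailed p={ks.pvalue:.3f} "
                             f"({ks.method})")
        else:
            lines.append("not run")
        path = out_dir / "report.md"
        path.write_text("\n".join(lines) + "\n")
        return StageReport("report", self._digest, [str(path)])


def run_pipeline_in_memory(config: RunConfig) -> PipelineRun:
    """Execute the configured stages in dependency order; returns the run
    object with in-memory artifacts and stage reports."""
    run = PipelineRun(config)
    run.out.mkdir(parents=True, exist_ok=True)
    handlers = {
        "simulate": run.simulate,
        "synteny": run.synteny_stage,
        "date": run.date_stage,
        "neutral": run.neutral_stage,
        "report": run.report_stage,
    }
    unknown = [s for s in config.stages if s not in handlers]
    if unknown:
        raise PipelineError(f"unknown stages: {unknown}")
    for stage in ("simulate", "synteny", "date", "neutral", "report"):
        if stage not in config.stages:
            continue
        log.info("stage %s: starting", stage)
        report = handlers[stage]()
        run.reports.append(report)
        for w in report.warnings:
            log.warning("stage %s: %s", stage, w)
        log.info("stage %s: %d output(s)", stage, len(report.outputs))
    return run


def run_pipeline(config: RunConfig) -> list[StageReport]:
    """Execute the configured stages and return their reports."""
    return run_pipeline_in_memory(config).reports
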