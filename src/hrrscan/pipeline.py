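"""End-to-end orchestration: QC -> diversity -> relationships -> runs ->
statistics -> islands, from a single YAML-serializable configuration.

Every stage writes its table under the configured output directory and
a provenance log records the config echo, package versions, the seed
and per-stage counts, so a run is reproducible from its log alone.
"""

from __future__ import annotations

import dataclasses
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import (GenotypeMatrix, QcParams, apply_qc, attach_groups,
                        qc_report_to_tsv, read_ped_map, subsample_breeds,
                        write_ped_map)
from .diversity import diversity_table, group_averages, breed_allele_freqs
from .relationships import (classical_mds, export_distances, ibs_distance,
                            mds_to_tsv, reynolds_distance)
from .detect import DetectionParams, detect_consecutive, detect_sliding, runs_to_tsv
from .runstats import (aggregate_group, genome_length_from_map,
                       method_correlation, summarize_breed)
from .islands import (call_islands, export_islands_bed, intersect_methods,
                      merge_across_breeds, select_top_snps, snp_incidence)


@dataclass
class RunConfig:
    """Full-pipeline configuration (defaults are the study settings)."""

    ped: str | None = None
    map: str | None = None
    groups: str | None = None          # optional breed->geo_group TSV
    simulate: dict | None = None       # SimConfig fields, alternative to ped/map
    outdir: str = "hrrscan_out"
    seed: int = 1
    max_per_breed: int = 30
    qc: dict = field(default_factory=dict)
    detection: dict = field(default_factory=dict)
    top_frac: float = 0.001
    island_min_snp: int = 4
    island_min_freq: float = 0.20
    island_merge_gap_bp: int = 1_000_000
    genome_bp: float | None = None     # override for D_HRR denominator
    mds_components: int = 10

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.simulate is None:
            if not self.ped or not self.map:
                raise ValueError("config needs either ped+map paths or a simulate block")
            for p in (self.ped, self.map, self.groups):
                if p and not Path(p).exists():
                    raise ValueError(f"input path does not exist: {p}")
        if not 0 < self.top_frac < 1:
            raise ValueError("top_frac must be in (0, 1)")
        if not 0 <= self.island_min_freq <= 1:
            raise ValueError("island_min_freq must be in [0, 1]")


def _load_inputs(cfg: RunConfig):
    if cfg.simulate is not None:
        from .simulate import SimConfig, generate_population
        sim = dict(cfg.simulate)
        sim.setdefault("seed", cfg.seed)
        if "islands" in sim:
            sim["islands"] = tuple(tuple(i) for i in sim["islands"])
        if "chrom_lengths_bp" in sim:
            sim["chrom_lengths_bp"] = tuple(sim["chrom_lengths_bp"])
        if "inbreeding" in sim and isinstance(sim["inbreeding"], list):
            sim["inbreeding"] = tuple(sim["inbreeding"])
        g, snpmap, samples, truth = generate_population(SimConfig(**sim))
        return g, snpmap, samples, truth
    g, snpmap, samples = read_ped_map(cfg.ped, cfg.map)
    if cfg.groups:
        gt = pd.read_csv(cfg.groups, sep="\t")
        samples = attach_groups(samples, dict(zip(gt["breed"], gt["geo_group"])))
    return g, snpmap, samples, None


def run_all(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns a summary dict of key results."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log: dict = {
        "hrrscan_version": __version__,
        "config": dataclasses.asdict(cfg),
        "stages": {},
    }

    def stage(name):
        log["stages"][name] = {}
        return log["stages"][name]

    try:
        g, snpmap, samples, truth = _load_inputs(cfg)
        st = stage("load")
        st.update(n_ind=g.n_ind, n_snp=g.n_snp)

        g, samples = subsample_breeds(g, samples, cfg.max_per_breed, cfg.seed)
        stage("subsample").update(n_ind=g.n_ind)

        q = QcParams(**cfg.qc)
        g, snpmap, qc_rep = apply_qc(g, snpmap, q)
        samples = samples[samples["sample_id"].isin(g.samples)].reset_index(drop=True)
        qc_report_to_tsv(qc_rep, out / "qc_report.tsv")
        stage("qc").update({k: v for k, v in qc_rep.items()
                            if k != "removed_individual_ids"})

        div = diversity_table(g, samples)
        div.to_csv(out / "diversity.tsv", sep="\t", index=False)
        grp = group_averages(div, samples)
        grp.to_csv(out / "diversity_groups.tsv", sep="\t", index=False)
        stage("diversity").update(n_breeds=len(div))

        d_ibs, labels = ibs_distance(g)
        k = min(cfg.mds_components, g.n_ind - 1)
        mds = classical_mds(d_ibs, k, labels)
        mds_to_tsv(mds, samples, out / "mds.tsv")
        freqs = breed_allele_freqs(g, samples, snp_ids=snpmap["snp_id"])
        d_rey, breeds = reynolds_distance(freqs)
        export_distances(d_rey, breeds, out / "reynolds.phy", fmt="phylip")
        export_distances(d_rey, breeds, out / "reynolds.nex", fmt="nexus")
        stage("relationships").update(
            mds_var_explained=[float(v) for v in mds.var_explained])

        p = DetectionParams(**cfg.detection)
        runs_cr = detect_consecutive(g, snpmap, p, samples)
        runs_sw = detect_sliding(g, snpmap, p, samples)
        runs_to_tsv(runs_cr, out / "runs_cr.tsv")
        runs_to_tsv(runs_sw, out / "runs_sw.tsv")
        stage("detect").update(total_cr=len(runs_cr), total_sw=len(runs_sw))

        genome_bp = cfg.genome_bp or genome_length_from_map(snpmap)
        b_cr = summarize_breed(runs_cr, samples, genome_bp, method="CR")
        b_sw = summarize_breed(runs_sw, samples, genome_bp, method="SW")
        pd.concat([b_cr, b_sw]).to_csv(out / "breed_summary.tsv", sep="\t", index=False)
        aggregate_group(b_cr, samples).to_csv(out / "group_summary_cr.tsv",
                                              sep="\t", index=False)
        corr = method_correlation(b_cr, b_sw)
        corr.to_csv(out / "method_correlation.tsv", sep="\t", header=True)
        stage("stats").update(genome_bp=float(genome_bp),
                              pearson_r={k: (None if np.isnan(v) else float(v))
                                         for k, v in corr.items()})

        inc_cr = snp_incidence(runs_cr, samples, snpmap, "CR")
        inc_sw = snp_incidence(runs_sw, samples, snpmap, "SW")
        sel = intersect_methods(select_top_snps(inc_cr, cfg.top_frac),
                                select_top_snps(inc_sw, cfg.top_frac))
        islands, diag = call_islands(
            sel, inc_cr, snpmap, min_snp=cfg.island_min_snp,
            min_freq=cfg.island_min_freq, merge_gap_bp=cfg.island_merge_gap_bp,
            runs=runs_cr)
        islands.drop(columns="snp_ids").to_csv(out / "islands.tsv",
                                               sep="\t", index=False)
        export_islands_bed(islands, out / "islands.bed")
        shared, tallies = merge_across_breeds(islands)
        shared.assign(breeds=shared["breeds"].map(",".join)).to_csv(
            out / "shared_islands.tsv", sep="\t", index=False)
        tallies.to_csv(out / "island_tallies.tsv", sep="\t", index=False)
        stage("islands").update(n_islands=len(islands),
                                n_shared=len(shared),
                                runs_hit=diag)
    except Exception as exc:
        failed = list(log["stages"])[-1] if log["stages"] else "load"
        raise RuntimeError(f"pipeline failed at stage {failed!r}: {exc}") from exc

    with open(out / "provenance.json", "w") as fh:
        json.dump(log, fh, indent=2, default=str)

    return {
        "g": g, "snpmap": snpmap, "samples": samples, "truth": truth,
        "diversity": div, "diversity_groups": grp,
        "mds": mds, "reynolds": (d_rey, breeds),
        "runs_cr": runs_cr, "runs_sw": runs_sw,
        "breed_cr": b_cr, "breed_sw": b_sw, "correlation": corr,
        "islands": islands, "shared_islands": shared, "tallies": tallies,
        "log": log,
    }
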