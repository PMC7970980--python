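"""Umbrella pipeline: simulate -> flow -> call -> chimera -> lineage -> report.

The pipeline chains the screening stages the way the field applies them to
a real cohort: every specimen's hemolymph is flow-classified; specimens
with an aneuploid peak (plus a few healthy controls) are genotyped by
simulated molecular cloning of EF1α and the control region and by direct
sequencing of COI; paired-tissue chimerism and the shared cancer genotype
yield the two-evidence BTN calls; shared cancer alleles are assigned to
lineages against the reference panel; cancer control regions are scanned
for recombination breakpoints.  Everything is deterministic given the seed.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import allelecall, chimera, flowploidy, io_, lineage, simcohort
from .errors import ConfigurationError

log = logging.getLogger("btnscreen")


@dataclass
class PipelineConfig:
    seed: int = 0
    stages: dict = field(
        default_factory=lambda: {
            "flow": True, "call": True, "chimera": True, "lineage": True
        }
    )
    simulate: dict = field(default_factory=dict)
    flow: dict = field(default_factory=dict)
    call: dict = field(default_factory=dict)
    chimera: dict = field(default_factory=dict)
    lineage: dict = field(default_factory=dict)
    n_genotyped_controls: int = 1
    chromatogram_minor_ratio: float = 0.2
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class PipelineReport:
    specimens: pd.DataFrame
    cancer_genotype: chimera.CancerGenotype
    btn_calls: list[chimera.BTNCall]
    lineage_calls: pd.DataFrame
    mito_groups: dict
    recombination: list[lineage.RecombinationReport]
    network: "object"
    config: PipelineConfig

    @property
    def n_btn_positive(self) -> int:
        return int(sum(c.positive for c in self.btn_calls))

    def summary(self) -> str:
        df = self.specimens
        n = len(df)
        n_dn = int((df.dn_status == flowploidy.DN_SUGGESTED).sum())
        lines = [
            "btn-screen pipeline summary",
            f"specimens screened: {n}",
            f"DN-suggested by flow cytometry: {n_dn} "
            f"({flowploidy.prevalence_percent(n_dn, n)}%)",
            f"genotyped individuals: {int(df.genotyped.sum())}",
            f"BTN-positive (two-evidence): {self.n_btn_positive}",
        ]
        for locus, shared in self.cancer_genotype.alleles.items():
            if shared:
                names = ", ".join(a.name for a in shared)
                lines.append(f"shared cancer alleles at {locus}: {names}")
        for locus, groups in self.mito_groups.items():
            if groups:
                parts = [f"{k}: {'/'.join(v)}" for k, v in sorted(groups.items())]
                lines.append(f"mito haplotype groups at {locus}: " + "; ".join(parts))
        if len(self.lineage_calls):
            for _, row in self.lineage_calls.iterrows():
                lines.append(
                    f"lineage {row.locus}-{row.allele}: {row.best_lineage} "
                    f"(d={row.n_diff}, p={row.p_dist:.4f})"
                )
        for rep in self.recombination:
            bp = ", ".join(str(b) for b in rep.breakpoints) or "none"
            lines.append(f"recombination {rep.query_name}: breakpoints {bp}")
        return "\n".join(lines) + "\n"

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.specimens.to_csv(out / "report.tsv", sep="\t", index=False, na_rep=".")
        (out / "summary.txt").write_text(self.summary())
        rows = [
            {
                "individual": c.individual_id,
                "chimeric": c.evidence["chimeric"],
                "positive": c.positive,
                "matched_loci": c.evidence["shared_alleles_matched"],
                "annotation": c.annotation or ".",
            }
            for c in self.btn_calls
        ]
        pd.DataFrame(rows).to_csv(out / "btn_calls.tsv", sep="\t", index=False)
        if len(self.lineage_calls):
            self.lineage_calls.to_csv(
                out / "lineage_calls.tsv", sep="\t", index=False
            )
        records = [
            (f"cancer|{locus}|{a.name}", a.sequence)
            for locus, shared in self.cancer_genotype.alleles.items()
            for a in shared
        ]
        if records:
            io_.write_fasta(records, out / "cancer_genotype.fasta")
        if self.network is not None and self.network.number_of_nodes():
            import networkx as nx

            edge_rows = [
                {"source": u, "target": v, "steps": d.get("steps", 1)}
                for u, v, d in self.network.edges(data=True)
            ]
            pd.DataFrame(edge_rows).to_csv(
                out / "network_edges.tsv", sep="\t", index=False
            )
            nx.write_graphml(self.network, out / "network.graphml")


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    logging.basicConfig(level=config.log_level)
    log.info("pipeline parameters: %s", config)
    sim_cfg = simcohort.SimulationConfig(seed=config.seed, **config.simulate)
    cohort = simcohort.generate_cohort(sim_cfg)
    panel = io_.load_reference_panel()
    rng = np.random.default_rng((config.seed * 0x5DEECE66D + 11) % (2**31))

    # ---- flow stage ----------------------------------------------------
    diagnoses = {}
    for sp in cohort.specimens:
        p = sp.flow_truth["neoplastic_fraction"]
        rp = sp.flow_truth["relative_ploidy"]
        events = simcohort.simulate_flow_events(
            p_aneu=p,
            relative_ploidy=rp if p > 0 else 4.0,
            flow_params=sim_cfg.flow_params,
            rng=rng,
            specimen_id=sp.id,
        )
        diagnoses[sp.id] = flowploidy.analyze_events(events, **config.flow)

    dn_ids = [
        sp.id
        for sp in cohort.specimens
        if diagnoses[sp.id].status == flowploidy.DN_SUGGESTED
    ]
    control_ids = [
        sp.id
        for sp in cohort.specimens
        if diagnoses[sp.id].status == flowploidy.HEALTHY
    ][: config.n_genotyped_controls]
    genotyped_ids = dn_ids + control_ids
    by_id = {sp.id: sp for sp in cohort.specimens}

    # ---- call stage ----------------------------------------------------
    call_cfg = dict(config.call)
    merge_homopolymers = call_cfg.pop("merge_homopolymers", True)
    panel_names = {
        (e.locus, e.sequence): e.allele_name
        for e in panel.entries
    }
    namer = allelecall.AlleleNamer(references=panel_names)
    genotypes: dict[str, dict[str, dict[str, allelecall.TissueGenotype]]] = {}
    clone_sets = []
    planned = []
    avoid = {
        a.sequence
        for sp in cohort.specimens
        for loci in sp.tissues.values()
        for g in loci.values()
        for a in g.retained()
    }
    for sid in genotyped_ids:
        sp = by_id[sid]
        planned.extend(
            [
                sp.genotype("hemolymph", "EF1a"),
                sp.genotype("foot", "EF1a"),
                sp.genotype("hemolymph", "CR"),
            ]
        )
    for truth_gt in planned:
        cs = simcohort.simulate_cloning(
            truth_gt,
            n_colonies=sim_cfg.n_colonies,
            artifact_rate=sim_cfg.artifact_rate,
            rng=rng,
            avoid=avoid,
        )
        clone_sets.append(cs)
    for cs in clone_sets:
        gt = allelecall.call_alleles(
            cs, cross_reference=clone_sets, namer=namer, **call_cfg
        )
        if merge_homopolymers:
            gt = allelecall.merge_homopolymer_variants(gt)
        genotypes.setdefault(gt.individual_id, {}).setdefault(gt.locus, {})[
            gt.tissue
        ] = gt

    # direct sequencing: foot CR and both tissues' COI
    for sid in genotyped_ids:
        sp = by_id[sid]
        per = genotypes.setdefault(sid, {})
        foot_cr = _direct_genotype(sp.genotype("foot", "CR"), namer)
        per.setdefault("CR", {})["foot"] = foot_cr
        foot_coi = _direct_genotype(sp.genotype("foot", "COI"), namer)
        per.setdefault("COI", {})["foot"] = foot_coi
        per["COI"]["hemolymph"] = _direct_hemolymph_coi(
            sp, foot_coi, namer, config.chromatogram_minor_ratio
        )

    # ---- chimera stage -------------------------------------------------
    chim_cfg = dict(config.chimera)
    match_min = chim_cfg.pop("match_min", 1)
    min_support = chim_cfg.pop("min_support", None)
    chim_results = {
        sid: chimera.detect_chimerism(genotypes[sid], **chim_cfg)
        for sid in genotyped_ids
    }
    dn_results = [chim_results[sid] for sid in dn_ids]
    btn_calls = []
    cancer = chimera.CancerGenotype()
    mito_groups: dict = {}
    if len(dn_results) >= 2:
        cancer = chimera.build_cancer_genotype(dn_results, min_support=min_support)
        mito_groups = chimera.mito_haplotype_groups(dn_results)
        if not cancer.empty:
            btn_calls = [
                chimera.call_btn(chim_results[sid], cancer, match_min=match_min)
                for sid in genotyped_ids
            ]

    # mitochondrial sexing from the mantle 16S genotype
    m_refs = [e.sequence for e in panel.entries
              if e.lineage == "host_M" and e.locus == "16S"]
    f_refs = [e.sequence for e in panel.entries
              if e.lineage == "host_F" and e.locus == "16S"]
    sexes = {
        sp.id: chimera.mito_sex(sp.genotype("mantle", "16S"), m_refs, f_refs)
        for sp in cohort.specimens
    }

    # ---- lineage stage -------------------------------------------------
    lin_cfg = dict(config.lineage)
    window = lin_cfg.pop("window", 50)
    step = lin_cfg.pop("step", 10)
    lineage_rows = []
    recomb_reports = []
    network = None
    if not cancer.empty:
        for locus, shared in cancer.alleles.items():
            for a in shared:
                call = lineage.assign_lineage(
                    a.sequence, panel, locus, allele_name=a.name, **lin_cfg
                )
                lineage_rows.append(
                    {
                        "locus": locus,
                        "allele": a.name,
                        "best_lineage": call.best_lineage
                        if not call.ambiguous
                        else "ambiguous",
                        "best_reference": call.best_reference or ".",
                        "n_diff": call.n_diff,
                        "p_dist": call.p_dist,
                        "novel": call.novel,
                    }
                )
        cr_f = next(e.sequence for e in panel.entries
                    if e.lineage == "host_F" and e.locus == "CR")
        cr_m = next(e.sequence for e in panel.entries
                    if e.lineage == "host_M" and e.locus == "CR")
        for a in cancer.alleles.get("CR", []):
            recomb_reports.append(
                lineage.scan_recombination(
                    a.sequence,
                    cr_f,
                    cr_m,
                    window=window,
                    step=step,
                    query_name=f"CR-{a.name}",
                    parent_names=("F-mtDNA", "M-mtDNA"),
                )
            )
        network = _coi_network(genotypes, cancer, genotyped_ids)

    # ---- report --------------------------------------------------------
    rows = []
    for sp in cohort.specimens:
        diag = diagnoses[sp.id]
        call = next(
            (c for c in btn_calls if c.individual_id == sp.id), None
        )
        rows.append(
            {
                "id": sp.id,
                "sex_true": sp.dui_sex_truth,
                "sex_mito": sexes[sp.id],
                "infected_truth": sp.infected,
                "neoplastic_fraction_truth": sp.flow_truth["neoplastic_fraction"],
                "dn_status": diag.status,
                "aneuploid_fraction": round(diag.aneuploid_fraction, 4),
                "genotyped": sp.id in genotyped_ids,
                "chimeric": chim_results[sp.id].chimeric
                if sp.id in chim_results
                else None,
                "btn_positive": call.positive if call else None,
                "matched_loci": call.evidence["shared_alleles_matched"]
                if call
                else None,
            }
        )
    return PipelineReport(
        specimens=pd.DataFrame(rows),
        cancer_genotype=cancer,
        btn_calls=btn_calls,
        lineage_calls=pd.DataFrame(lineage_rows),
        mito_groups=mito_groups,
        recombination=recomb_reports,
        network=network,
        config=config,
    )


def _direct_genotype(truth_gt, namer) -> allelecall.TissueGenotype:
    """Direct Sanger sequencing of a (near-)homoplasmic tissue: the dominant
    allele is read; minority templates below chromatogram visibility are not."""
    top = max(truth_gt.retained(), key=lambda a: a.frequency)
    call = allelecall.AlleleCall(
        allele_id=namer.name(truth_gt.locus, top.sequence),
        sequence=top.sequence,
        colony_count=0,
        frequency=1.0,
        status=allelecall.COMMON,
    )
    return allelecall.TissueGenotype(
        individual_id=truth_gt.individual_id,
        locus=truth_gt.locus,
        tissue=truth_gt.tissue,
        alleles=[call],
        heteroplasmic=False,
    )


def _direct_hemolymph_coi(sp, foot_coi, namer, minor_ratio):
    """COI by direct sequencing of hemolymph: piggyback peaks resolved into
    a dominant and a minority sequence, attributed via the foot allele."""
    truth = sp.genotype("hemolymph", "COI")
    ranked = sorted(truth.retained(), key=lambda a: -a.frequency)
    foot_seq = foot_coi.retained()[0].sequence
    if len(ranked) == 1:
        return _direct_genotype(truth, namer)
    major, minor = ranked[0], ranked[1]
    ratio = min(max(minor.frequency, 0.01), 0.45)
    sites = simcohort.simulate_chromatogram(major.sequence, minor.sequence, ratio)
    res = allelecall.resolve_piggyback(sites, foot_allele=foot_seq)
    alleles = [
        allelecall.AlleleCall(
            allele_id=namer.name("COI", res.dominant),
            sequence=res.dominant,
            colony_count=0,
            frequency=major.frequency,
            status=allelecall.COMMON,
        ),
        allelecall.AlleleCall(
            allele_id=namer.name("COI", res.minority),
            sequence=res.minority,
            colony_count=0,
            frequency=minor.frequency,
            status=allelecall.RARE,
        ),
    ]
    return allelecall.TissueGenotype(
        individual_id=sp.id,
        locus="COI",
        tissue="hemolymph",
        alleles=alleles,
        heteroplasmic=True,
    )


def _coi_network(genotypes, cancer, genotyped_ids):
    """Haplotype network over every COI allele observed in the cohort."""
    cancer_seqs = cancer.sequences("COI")
    haps: dict[str, lineage.Haplotype] = {}
    counter = 0
    for sid in genotyped_ids:
        coi = genotypes.get(sid, {}).get("COI", {})
        for tissue, gt in coi.items():
            for a in gt.retained():
                if a.sequence not in haps:
                    counter += 1
                    haps[a.sequence] = lineage.Haplotype(
                        id=f"COI-{a.allele_id}",
                        sequence=a.sequence,
                        frequency=0,
                    )
                h = haps[a.sequence]
                h.frequency += 1
                group = "cancer" if a.sequence in cancer_seqs else "host"
                h.group_counts[group] = h.group_counts.get(group, 0) + 1
    if not haps:
        return None
    return lineage.build_haplotype_network(list(haps.values()))
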