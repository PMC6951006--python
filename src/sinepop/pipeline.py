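"""End-to-end pipeline wiring and run manifest.

``run_all`` executes simulate -> annotate -> tsd/flanks -> excision ->
popgen -> copynumber on a seeded synthetic study and writes every artifact
with a sha256 checksum to a manifest, so identical seed + config yield
identical manifests.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from sinepop import tables
from sinepop.io import (
    LocusTable,
    SequenceRecord,
    read_fasta,
    write_fasta,
    read_genotypes,
    write_genotypes,
    write_newick,
)
from sinepop.annotate import SineConsensus, annotate_element, fold_hairpin, survey_transcripts
from sinepop.forensics import LocusAlleles, call_tsd, flank_tandem_repeats, flank_composition
from sinepop.excision import call_footprint, summarize_footprints
from sinepop.popgen import (
    locus_stats,
    stats_frame,
    frequencies_frame,
    ecotype_stats,
    nei_distance,
    nj_tree,
    amova,
)
from sinepop.qpcr import quantify_plate, compare_groups
from sinepop.simulate import (
    SimConfig,
    make_consensus,
    plant_insertion,
    plant_excision,
    simulate_genotypes,
    simulate_qpcr,
    simulate_transcripts,
    table1_fixture,
    truth_frame,
)

log = logging.getLogger("sinepop")

DEFAULT_GROUPING = {p: ("resident" if p in tables.ECOTYPE_GROUPS["resident"] else "migratory")
                    for p in tables.POPULATIONS}


@dataclass
class RunConfig:
    """One reproducible pipeline run: seed, stage toggles, popgen options."""

    seed: int = 0
    out_dir: str = "sinepop_run"
    sim: SimConfig = field(default_factory=SimConfig)
    grouping: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_GROUPING))
    distance_method: str = "nei1972"
    n_permutations: int = 999
    stages: dict[str, bool] = field(
        default_factory=lambda: {
            "simulate": True, "annotate": True, "forensics": True,
            "excision": True, "popgen": True, "copynumber": True,
        }
    )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        cfg = cls(sim=sim, **{k: v for k, v in raw.items() if k != "sim"})
        cfg.sim.seed = cfg.seed
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def loci_from_files(fasta_path: str, spans_path: str) -> list[LocusAlleles]:
    """Assemble LocusAlleles from a FASTA with ``.filled``/``.empty`` id
    suffixes and an element-span TSV (locus_id, start, end)."""
    records = {r.id: r for r in read_fasta(fasta_path)}
    spans = pd.read_csv(spans_path, sep="\t")
    loci = []
    for _, row in spans.iterrows():
        lid = str(row["locus_id"])
        filled = records.get(f"{lid}.filled")
        if filled is None:
            raise ValueError(f"{fasta_path}: no record {lid}.filled")
        loci.append(
            LocusAlleles(
                locus_id=lid,
                filled=filled,
                element_span=(int(row["start"]), int(row["end"])),
                empty=records.get(f"{lid}.empty"),
            )
        )
    return loci


def simulate_stage(cfg: RunConfig, out: str) -> dict[str, str]:
    """Generate the full synthetic study into ``out``; returns artifact paths."""
    sim = cfg.sim
    rng = sim.rng()
    consensus = make_consensus(sim.seed)
    loci, ins_truths, exc_records, exc_truths = [], [], [], []
    n_excised = int(round(sim.excision_fraction * sim.n_loci))
    for i in range(sim.n_loci):
        locus, truth = plant_insertion(consensus, sim, rng, locus_id=f"L{i + 1:03d}")
        loci.append(locus)
        ins_truths.append(truth)
        if i < n_excised:
            unit = ["TG", "CA", "A", "CT"][int(rng.integers(0, 4))]
            copies = int(rng.integers(5, 46))
            mh = int(rng.integers(0, 9))
            excised, etruth = plant_excision(locus, unit, copies, mh, rng)
            exc_records.append(excised)
            exc_truths.append(etruth)

    freqs = {
        pop: {locus: tables.TABLE1[locus][pop][0] for locus in tables.LOCI}
        for pop in tables.POPULATIONS
    }
    genotypes = simulate_genotypes(freqs, sim.n_ind_per_pop, rng)

    # standards are precise plasmid dilutions (published curve R^2 = 0.999);
    # unknowns carry the configured sample-level Ct noise
    standards = simulate_qpcr(
        [3, 4, 5, 6, 7, 8, 9], tables.QPCR_SLOPE, tables.QPCR_INTERCEPT,
        min(sim.ct_noise_sd, 0.05), rng, n_replicates=3, role="standard",
    )
    unknown_rows = []
    for pop in tables.POPULATIONS:
        eco = cfg.grouping.get(pop, "migratory")
        true_cpg = tables.COPYNUMBER_RESIDENT if eco == "resident" else tables.COPYNUMBER_MIGRATORY
        mass = 10000.0
        for k in range(1, 4):  # three biological samples per population
            copies = true_cpg * mass / tables.GENOME_SIZE_PG
            unknown_rows.append(
                simulate_qpcr(
                    [np.log10(copies)], tables.QPCR_SLOPE, tables.QPCR_INTERCEPT,
                    sim.ct_noise_sd, rng, n_replicates=3, role="unknown",
                    sample_ids=[f"{pop}_{k}"], input_mass_pg=mass,
                )
            )
    plate = pd.concat([standards] + unknown_rows, ignore_index=True)

    contigs, planted = simulate_transcripts(
        consensus, n_full=3, n_partial_by_region={"trna": 2, "body": 2, "tail": 7}, rng=rng
    )

    paths = {}

    def save(name, fn):
        path = os.path.join(out, name)
        fn(path)
        paths[name] = path
        return path

    save("consensus.fasta", lambda p: write_fasta([consensus.record], p))
    allele_records = []
    for locus in loci:
        allele_records.append(locus.filled)
        allele_records.append(locus.empty)
    save("loci.fasta", lambda p: write_fasta(allele_records, p))
    spans = pd.DataFrame(
        [
            {"locus_id": l.locus_id, "start": l.element_span[0], "end": l.element_span[1]}
            for l in loci
        ]
    )
    save("element_spans.tsv", lambda p: spans.to_csv(p, sep="\t", index=False))
    save("excised.fasta", lambda p: write_fasta(exc_records, p))
    save("genotypes.tsv", lambda p: write_genotypes(genotypes, p))
    save("qpcr_plate.tsv", lambda p: plate.to_csv(p, sep="\t", index=False))
    save("contigs.fasta", lambda p: write_fasta(contigs, p))
    save("truth_insertions.tsv", lambda p: truth_frame(ins_truths).to_csv(p, sep="\t", index=False))
    if exc_truths:
        save("truth_excisions.tsv", lambda p: truth_frame(exc_truths).to_csv(p, sep="\t", index=False))
    return paths


def run_all(cfg: RunConfig) -> pd.DataFrame:
    """Execute every enabled stage; returns the manifest frame.

    Any stage failure aborts with the stage name and offending input in the
    exception message.  The manifest lists (stage, artifact, path, sha256).
    """
    os.makedirs(cfg.out_dir, exist_ok=True)
    manifest_rows = []
    artifacts: dict[str, str] = {}

    def record(stage: str, paths: dict[str, str]) -> None:
        for name, path in paths.items():
            artifacts[name] = path
            manifest_rows.append(
                {"stage": stage, "artifact": name, "path": path, "sha256": _sha256(path)}
            )

    def need(stage: str, name: str) -> str:
        if name not in artifacts:
            raise RuntimeError(
                f"stage {stage!r}: required input {name!r} missing "
                "(produced by a disabled stage?)"
            )
        return artifacts[name]

    def run_stage(name: str, fn) -> None:
        if not cfg.stages.get(name, True):
            log.info("stage %s disabled", name)
            return
        log.info("stage %s", name)
        try:
            record(name, fn())
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    run_stage("simulate", lambda: simulate_stage(cfg, cfg.out_dir))

    def annotate_fn():
        consensus = SineConsensus(record=read_fasta(need("annotate", "consensus.fasta"))[0])
        loci = loci_from_files(need("annotate", "loci.fasta"), need("annotate", "element_spans.tsv"))
        rows, hairpins = [], []
        for locus in loci:
            ann = annotate_element(
                SequenceRecord(id=locus.locus_id, seq=locus.element_seq), consensus
            )
            rows.append(
                {
                    "element_id": ann.element_id,
                    "percent_identity": ann.percent_identity,
                    "body_identity": ann.body_identity,
                    "tail_motif": ann.tail_motif,
                    "tgtaa_copies": ann.tgtaa_copies,
                    "family_member": ann.family_member,
                    "n_body_indels": len(ann.body_indels),
                }
            )
            lo, hi = ann.region_spans["tail"]
            tail = locus.element_seq[lo:hi]
            if 10 <= len(tail) <= 400:
                hp = fold_hairpin(tail)
                hairpins.append(
                    {
                        "element_id": ann.element_id,
                        "stem_length": hp.stem_length,
                        "loop_start": hp.loop_span[0],
                        "loop_end": hp.loop_span[1],
                        "n_pairs": len(hp.pairs),
                    }
                )
        counts = survey_transcripts(read_fasta(need("annotate", "contigs.fasta")), consensus)
        out = {}
        p1 = os.path.join(cfg.out_dir, "annotations.tsv")
        pd.DataFrame(rows).to_csv(p1, sep="\t", index=False)
        out["annotations.tsv"] = p1
        p2 = os.path.join(cfg.out_dir, "hairpins.tsv")
        pd.DataFrame(hairpins).to_csv(p2, sep="\t", index=False)
        out["hairpins.tsv"] = p2
        p3 = os.path.join(cfg.out_dir, "transcript_hits.tsv")
        pd.DataFrame(
            [{"region": k, "hits": v} for k, v in counts.hits_per_region.items()]
            + [{"region": "full_length", "hits": counts.n_full_length}]
        ).to_csv(p3, sep="\t", index=False)
        out["transcript_hits.tsv"] = p3
        return out

    run_stage("annotate", annotate_fn)

    def forensics_fn():
        loci = loci_from_files(need("forensics", "loci.fasta"), need("forensics", "element_spans.tsv"))
        tsd_rows, tr_rows = [], []
        for locus in loci:
            tsd = call_tsd(locus)
            tsd_rows.append(
                {
                    "locus_id": locus.locus_id,
                    "tsd_len": tsd.length if tsd else 0,
                    "tsd_seq": tsd.sequence if tsd else "",
                }
            )
            for call in flank_tandem_repeats(locus):
                tr_rows.append(
                    {
                        "locus_id": locus.locus_id,
                        "flank": call.flank,
                        "unit": call.unit,
                        "copies": call.copies,
                        "offset": call.offset,
                    }
                )
        comp = flank_composition(loci)
        out = {}
        p1 = os.path.join(cfg.out_dir, "tsd_calls.tsv")
        pd.DataFrame(tsd_rows).to_csv(p1, sep="\t", index=False)
        out["tsd_calls.tsv"] = p1
        p2 = os.path.join(cfg.out_dir, "tandem_repeats.tsv")
        pd.DataFrame(tr_rows).to_csv(p2, sep="\t", index=False)
        out["tandem_repeats.tsv"] = p2
        p3 = os.path.join(cfg.out_dir, "flank_composition.tsv")
        pd.DataFrame(
            [
                {"side": "5prime", "mean_at": comp.mean_5prime, "t": comp.t_5prime, "p": comp.p_5prime},
                {"side": "3prime", "mean_at": comp.mean_3prime, "t": comp.t_3prime, "p": comp.p_3prime},
            ]
        ).to_csv(p3, sep="\t", index=False)
        out["flank_composition.tsv"] = p3
        return out

    run_stage("forensics", forensics_fn)

    def excision_fn():
        loci = {
            l.locus_id: l
            for l in loci_from_files(
                need("excision", "loci.fasta"), need("excision", "element_spans.tsv")
            )
        }
        excised = read_fasta(need("excision", "excised.fasta"))
        footprints = []
        for rec in excised:
            lid = rec.id.removesuffix(".excised")
            footprints.append(call_footprint(loci[lid], rec))
        df = summarize_footprints(footprints)
        path = os.path.join(cfg.out_dir, "footprints.tsv")
        df.to_csv(path, sep="\t", index=False)
        return {"footprints.tsv": path}

    run_stage("excision", excision_fn)

    def popgen_fn():
        table = read_genotypes(need("popgen", "genotypes.tsv"))
        stats = locus_stats(table)
        out = {}
        p1 = os.path.join(cfg.out_dir, "locus_stats.tsv")
        stats_frame(stats).to_csv(p1, sep="\t", index=False)
        out["locus_stats.tsv"] = p1
        eco_stats, eco_means = ecotype_stats(table, cfg.grouping)
        p2 = os.path.join(cfg.out_dir, "ecotype_stats.tsv")
        df = stats_frame(eco_stats)
        df.to_csv(p2, sep="\t", index=False)
        out["ecotype_stats.tsv"] = p2
        freqs = frequencies_frame(stats).dropna()
        dist = nei_distance(freqs, method=cfg.distance_method)
        p3 = os.path.join(cfg.out_dir, "nei_distances.tsv")
        pd.DataFrame(dist.d, index=dist.labels, columns=dist.labels).to_csv(p3, sep="\t")
        out["nei_distances.tsv"] = p3
        tree = nj_tree(dist)
        p4 = os.path.join(cfg.out_dir, "nj_tree.nwk")
        write_newick(tree, p4)
        out["nj_tree.nwk"] = p4
        res = amova(table, cfg.grouping, n_permutations=cfg.n_permutations, seed=cfg.seed)
        p5 = os.path.join(cfg.out_dir, "amova.tsv")
        pd.DataFrame([asdict(res) | {"percentages": list(res.percentages)}]).to_csv(
            p5, sep="\t", index=False
        )
        out["amova.tsv"] = p5
        return out

    run_stage("popgen", popgen_fn)

    def copynumber_fn():
        plate = pd.read_csv(need("copynumber", "qpcr_plate.tsv"), sep="\t")
        curve, estimates = quantify_plate(plate)
        out = {}
        p1 = os.path.join(cfg.out_dir, "copy_numbers.tsv")
        pd.DataFrame([asdict(e) for e in estimates]).to_csv(p1, sep="\t", index=False)
        out["copy_numbers.tsv"] = p1
        comparison = None
        if all(e.sample_id.split("_")[0] in cfg.grouping for e in estimates):
            try:
                comparison = compare_groups(estimates, cfg.grouping)
            except ValueError:
                pass  # too few estimates per group for an ANOVA
        p2 = os.path.join(cfg.out_dir, "standard_curve.tsv")
        pd.DataFrame(
            [{"slope": curve.slope, "intercept": curve.intercept, "r2": curve.r2, "n": curve.n_points}]
        ).to_csv(p2, sep="\t", index=False)
        out["standard_curve.tsv"] = p2
        if comparison is not None:
            p3 = os.path.join(cfg.out_dir, "copy_number_groups.tsv")
            rows = [
                {"level": "ecotype", "name": k, "mean": v}
                for k, v in comparison["ecotype_means"].items()
            ] + [
                {"level": "population", "name": k, "mean": v}
                for k, v in comparison["population_means"].items()
            ]
            pd.DataFrame(rows).to_csv(p3, sep="\t", index=False)
            out["copy_number_groups.tsv"] = p3
        return out

    run_stage("copynumber", copynumber_fn)

    manifest = pd.DataFrame(manifest_rows, columns=["stage", "artifact", "path", "sha256"])
    manifest_path = os.path.join(cfg.out_dir, "manifest.tsv")
    manifest.to_csv(manifest_path, sep="\t", index=False)
    return manifest
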