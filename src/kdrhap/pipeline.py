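"""End-to-end orchestration of the analysis stages with a manifest.

Stages: codon-effect annotation -> allele frequencies and the >=5% filter
-> pairwise D' -> haplotype grouping (hierarchical + median-joining
network) and concordance -> selection scans (core haplotypes, EHH,
windowed homozygosity, shared lengths) -> heterozygote-excess test ->
surveillance panel design.  Outputs are plain-text tables plus a JSON
manifest recording files, parameters, seeds and checksums; a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import assay, groups, popgen, selection
from . import io as kio
from .genemodel import GeneModel, annotate_codon_effect
from .hapmatrix import HaplotypeMatrix
from .simulate import SimulatedCohort, SweepSimConfig, generate_cohort

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Inputs, stage toggles and stage parameters for one pipeline run.

    Either file paths (``vcf``/``gff3``/``fasta``/``metadata``) or a
    simulation config must be provided.  Intervals are 1-based,
    end-exclusive.
    """

    outdir: str
    seed: int = 0
    # inputs
    vcf: str | None = None
    gff3: str | None = None
    fasta: str | None = None
    metadata: str | None = None
    sim_config: SweepSimConfig | None = None
    # region structure (taken from sim config when simulating)
    gene_interval: tuple[int, int] | None = None
    core_interval: tuple[int, int] | None = None
    focal_sites: dict[str, int] = field(default_factory=dict)
    # stage toggles
    stages: tuple[str, ...] = (
        "annotate",
        "freqs",
        "ld",
        "groups",
        "selection",
        "hetexcess",
        "panel",
    )
    # parameters
    frequency_threshold: float = 0.05
    cut_height: float = 5.0
    linkage_method: str = "average"
    min_group_size: int = 3
    max_edge_dist: int = 2
    core_min_frequency: float = 0.01
    map_rate_cm_per_mb: float = 1.0
    n_windows: int = 50
    bootstrap_reps: int = 500
    het_reps: int = 100_000
    k_folds: int = 5
    cv_repeats: int = 3
    tree_max_depth: int = 14
    panel_flank: int = 10_000


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _focal_carriage(haps: HaplotypeMatrix, focal_sites: dict[str, int]) -> dict[str, np.ndarray]:
    lookup = haps.site_lookup()
    out = {}
    for base, pos in focal_sites.items():
        if pos in lookup:
            out[base] = haps.codes[lookup[pos]] > 0
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the toggled stages and return the manifest dict."""
    outdir = kio.ensure_dir(config.outdir)
    manifest: dict = {
        "parameters": {
            k: v
            for k, v in dataclasses.asdict(config).items()
            if k not in ("sim_config",)
        },
        "seed": config.seed,
        "outputs": {},
        "failures": [],
    }

    # ---- load or simulate inputs
    cohort: SimulatedCohort | None = None
    if config.sim_config is not None:
        cohort = generate_cohort(config.sim_config)
        paths = cohort.write(outdir / "inputs")
        manifest["outputs"]["inputs"] = {k: str(p) for k, p in paths.items()}
        haps = cohort.haplotypes
        models: list[GeneModel] = [cohort.gene_model]
        reference = cohort.reference
        chrom = cohort.config.chrom
        gene = config.gene_interval or cohort.config.gene_interval
        core = config.core_interval or cohort.config.core_interval
        focal_sites = config.focal_sites or cohort.truth.focal_sites
        region = (1, cohort.config.region_length + 1)
    else:
        if not all((config.vcf, config.gff3, config.fasta, config.metadata)):
            raise ValueError("either sim_config or all four input paths are required")
        reference_by_chrom = kio.read_fasta(config.fasta)
        models = kio.read_gff3_models(config.gff3)
        meta = kio.read_metadata(config.metadata)
        haps = kio.read_phased_vcf(config.vcf, meta)
        chrom = models[0].chrom
        reference = reference_by_chrom[chrom]
        if config.gene_interval is None or config.core_interval is None:
            raise ValueError("gene_interval and core_interval required for file inputs")
        gene = config.gene_interval
        core = config.core_interval
        focal_sites = config.focal_sites
        region = (1, len(reference) + 1)

    model = models[0]
    focal_carriage = _focal_carriage(haps, focal_sites)

    def record(stage: str, name: str, path: Path) -> None:
        manifest["outputs"].setdefault(stage, {})[name] = {
            "path": str(path),
            "sha256": _sha256(path),
        }

    effects = {}
    for i, site in enumerate(haps.sites):
        eff = annotate_codon_effect(site, 0, model, reference)
        effects[i] = eff

    # ---- annotate
    if "annotate" in config.stages:
        path = outdir / "annotation.tsv"
        kio.write_annotation_table(path, [(haps.sites[i], 0, effects[i]) for i in effects])
        record("annotate", "annotation", path)

    # ---- frequencies + filter
    freq_table = popgen.allele_frequencies(haps)
    if "freqs" in config.stages:
        path = outdir / "allele_frequencies.tsv"
        freq_table.to_csv(path, sep="\t", index=False, float_format="%.6f")
        record("freqs", "allele_frequencies", path)
        filtered = popgen.filter_by_max_frequency(freq_table, config.frequency_threshold)
        missense_rows = {
            i for i, e in effects.items()
            if not isinstance(e, str) and e.effect_class in ("missense", "nonsense")
        }
        pos_to_row = haps.site_lookup()
        path2 = outdir / "nonsynonymous_filtered.tsv"
        filtered.iloc[[i for i, r in enumerate(filtered.itertuples()) if pos_to_row.get(r.pos) in missense_rows]].to_csv(
            path2, sep="\t", index=False, float_format="%.6f"
        )
        record("freqs", "nonsynonymous_filtered", path2)

    # ---- LD
    if "ld" in config.stages:
        pos_to_row = haps.site_lookup()
        alleles = [
            (i, 0) for i, e in effects.items()
            if not isinstance(e, str) and e.effect_class in ("missense", "nonsense")
            and 0 < haps.allele_counts(i)[1:].sum() < haps.n_haplotypes
        ]
        alleles = alleles[:60]  # cap the matrix for very dense inputs
        dmat = popgen.dprime_matrix(haps, alleles)
        path = outdir / "dprime_matrix.tsv"
        dmat.to_csv(path, sep="\t", float_format="%.4f")
        record("ld", "dprime_matrix", path)

    # ---- grouping
    assignment_h = None
    if "groups" in config.stages:
        dist = groups.pairwise_hamming(haps, window=gene)
        assignment_h = groups.hierarchical_groups(
            dist,
            focal_carriage,
            method=config.linkage_method,
            cut_height=config.cut_height,
            min_group_size=config.min_group_size,
        )
        if focal_carriage:
            resistant = np.nonzero(
                np.any([c for c in focal_carriage.values()], axis=0)
            )[0]
        else:
            resistant = np.array([], dtype=int)
        assignment_n = ["wt"] * haps.n_haplotypes
        if resistant.size:
            biallelic = haps.biallelic_mask()
            rows_gene = haps.site_index_in(*gene)
            rows_gene = rows_gene[biallelic[rows_gene]]
            net = groups.median_joining_network(
                haps.take_sites(rows_gene),
                hap_subset=resistant,
                max_edge_dist=config.max_edge_dist,
            )
            net.window_rows = rows_gene  # rows in the full matrix
            groups.annotate_nonsynonymous_edges(net, effects)
            comp = net.component_ids()
            net_labels_sub = groups.label_clusters(
                comp[resistant] + 1,
                {b: np.asarray(c)[resistant] for b, c in focal_carriage.items()},
                config.min_group_size,
            )
            for idx, lab in zip(resistant, net_labels_sub):
                assignment_n[idx] = lab
            path3 = outdir / "network.gml"
            groups.export_network(net, gml_path=path3)
            record("groups", "network_gml", path3)
        conc = groups.concordance(assignment_h, assignment_n)
        path = outdir / "group_assignments.tsv"
        import pandas as pd

        pd.DataFrame(
            {
                "haplotype": np.arange(haps.n_haplotypes),
                "hierarchical": assignment_h,
                "network": assignment_n,
            }
        ).to_csv(path, sep="\t", index=False)
        record("groups", "assignments", path)
        ftab = groups.group_frequency_table(haps, assignment_h)
        path2 = outdir / "group_frequencies.tsv"
        ftab.to_csv(path2, sep="\t", float_format="%.4f")
        record("groups", "frequencies", path2)
        manifest["concordance"] = conc

    # ---- selection scans
    if "selection" in config.stages:
        core_set = selection.define_core_haplotypes(
            haps, core, config.core_min_frequency, focal_carriage
        )
        gmap = selection.GeneticMap.constant(*region, rate=config.map_rate_cm_per_mb)
        curves = []
        for cid, label in enumerate(core_set.labels):
            if core_set.carriers[cid].size < 2:
                continue
            for direction in ("upstream", "downstream"):
                curve = selection.ehh_decay(
                    haps, core_set, cid, direction, effects=effects
                )
                frame = curve.as_frame()
                frame["label"] = label
                curves.append(frame)
        import pandas as pd

        path = outdir / "ehh_curves.tsv"
        pd.concat(curves).to_csv(path, sep="\t", index=False, float_format="%.6f")
        record("selection", "ehh", path)

        width = (region[1] - region[0]) // config.n_windows
        windows = [
            (region[0] + k * width, region[0] + (k + 1) * width)
            for k in range(config.n_windows)
        ]
        hh = []
        for cid, label in enumerate(core_set.labels):
            if core_set.carriers[cid].size < 2:
                continue
            frame = selection.window_homozygosity(haps, windows, core_set.carriers[cid])
            frame["label"] = label
            hh.append(frame)
        path2 = outdir / "window_homozygosity.tsv"
        pd.concat(hh).to_csv(path2, sep="\t", index=False, float_format="%.6f")
        record("selection", "window_homozygosity", path2)

        shared = {}
        for cid, label in enumerate(core_set.labels):
            if label.startswith("wt") or core_set.carriers[cid].size < 2:
                continue
            res = selection.shared_haplotype_lengths(
                haps,
                core_set.carriers[cid],
                core,
                gmap,
                effects=effects,
                bootstrap_reps=config.bootstrap_reps,
                seed=config.seed,
                label=label,
            )
            years = haps.meta["year"].to_numpy()[core_set.carriers[cid]]
            shared[label] = dict(
                median_cm=res.median_cm,
                ci=res.ci,
                n_pairs=int(res.lengths_cm.size),
                n_censored=res.n_censored,
                first_year=int(years.min()),
            )
        path3 = outdir / "shared_lengths.json"
        path3.write_text(json.dumps(shared, indent=2))
        record("selection", "shared_lengths", path3)
        if len(shared) >= 3:
            r, p, defined = selection.detection_year_correlation(
                {k: (v["first_year"], v["median_cm"]) for k, v in shared.items()}
            )
            manifest["detection_year_correlation"] = {
                "r": r if defined else None,
                "p": p if defined else None,
            }

    # ---- het excess
    if "hetexcess" in config.stages and {"F", "S"} <= set(focal_carriage):
        f = focal_carriage["F"]
        s = focal_carriage["S"]
        pops_with_both = [
            p for p in haps.populations()
            if f[haps.population_haplotypes(p)].any()
            and s[haps.population_haplotypes(p)].any()
        ]
        results = {}
        for pop in pops_with_both:
            idx = haps.population_haplotypes(pop)
            c_f = int(f[idx].sum())
            c_s = int(s[idx].sum())
            c_wt = int(idx.size - c_f - c_s)
            n = idx.size // 2
            obs = 0
            for k in range(n):
                a, b = idx[2 * k], idx[2 * k + 1]
                if (f[a] and s[b]) or (s[a] and f[b]):
                    obs += 1
            res = popgen.het_excess_test(
                c_f, c_s, c_wt, n, obs, reps=config.het_reps, seed=config.seed
            )
            results[pop] = dataclasses.asdict(res)
        path = outdir / "het_excess.json"
        path.write_text(json.dumps(results, indent=2))
        record("hetexcess", "het_excess", path)

    # ---- panel design
    if "panel" in config.stages and assignment_h is not None:
        panel = assay.panel_frequency_table(
            haps, assignment_h, gene, flank=config.panel_flank
        )
        path = outdir / "panel_report.tsv"
        panel.to_csv(path, sep="\t", index=False, float_format="%.4f")
        record("panel", "panel_report", path)
        data = assay.LabelledFeatureMatrix.from_haplotypes(
            haps,
            assignment_h,
            region=(gene[0] - config.panel_flank, gene[1] + config.panel_flank),
            merge_to_wildtype=("wt", "OR"),
        )
        cv = assay.stratified_cv_accuracy(
            data,
            max_depth=config.tree_max_depth,
            k_folds=config.k_folds,
            repeats=config.cv_repeats,
            seed=config.seed,
        )
        path2 = outdir / "cv_results.json"
        path2.write_text(cv.to_json(orient="records", indent=2))
        record("panel", "cv_results", path2)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
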