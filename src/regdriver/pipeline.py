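"""End-to-end orchestration: cohort files in, driver candidates out.

``run_all`` executes the stages in dependency order — variant QC, region
definition and filtering, background-model fit and recurrence testing
(promoters and CREs as separate batches), SNV expression effects, CNV
karyotyping and CNV-at-CRE tests, mutational signatures and AID motifs,
and subgroup statistics — writing versioned TSV outputs and a JSON report
with record counts in and out of every filter.  Identical inputs and seed
give an identical report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cnv as cnvmod
from . import recurrence as rec
from . import signatures as sig
from . import stats as st
from .expression import ExpressionMatrix, de_pipeline
from .regions import (
    CREFragment,
    GenomicInterval,
    define_promoters,
    filter_interactions,
    mappability_filter,
)
from .variants import filter_variant_frame, read_maf

logger = logging.getLogger(__name__)


@dataclass
class Thresholds:
    """Analysis constants; defaults are the published values."""

    chicago_min: float = 5.0
    distance_max: float = 1e6
    mappability_min: float = 0.95
    focal_log2: float = 0.1613
    focal_size: float = 3e6
    fc_up: float = 1.2
    fc_down: float = 0.8
    q_recurrence: float = 0.05
    q_de: float = 0.1
    min_mutated: int = 3
    min_cnv_group: int = 7
    n_perm: int = 10_000
    aar_min: float = 0.2


@dataclass
class RunConfig:
    cohort_dir: str
    out_dir: str
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    subgroups: tuple[str, ...] = st.SUBGROUPS
    gene_body_pad: int = 1000  # gene interval = TSS +/- pad for CNV overlap

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = Thresholds(**raw.pop("thresholds", {}))
        defaults = asdict(Thresholds())
        for k, v in asdict(th).items():
            if v != defaults[k]:
                logger.warning("threshold override: %s = %s", k, v)
        return cls(thresholds=th, **raw)

    def hash(self) -> str:
        """Hash of the analysis parameters (paths excluded): identical
        settings give identical hashes regardless of file locations."""
        blob = asdict(self)
        blob.pop("cohort_dir"), blob.pop("out_dir")
        return hashlib.sha256(
            json.dumps(blob, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def _gene_intervals(tss: pd.DataFrame, pad: int) -> dict[str, GenomicInterval]:
    out = {}
    for r in tss.itertuples(index=False):
        t0 = int(r.tss) - 1
        out[r.gene] = GenomicInterval(r.chrom, max(0, t0 - pad), t0 + pad + 1)
    return out


def run_all(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written as JSON)."""
    cdir = Path(config.cohort_dir)
    odir = Path(config.out_dir)
    odir.mkdir(parents=True, exist_ok=True)
    th = config.thresholds
    chash = config.hash()
    report: dict = {"config_hash": chash, "seed": config.seed, "stages": {}}

    current = {"name": "inputs"}

    def stage(name):
        current["name"] = name
        report["stages"][name] = {}
        return report["stages"][name]

    try:
        # ---- inputs
        tss = pd.read_csv(cdir / "tss.tsv", sep="\t", dtype={"chrom": str})
        interactions = pd.read_csv(cdir / "interactions.tsv", sep="\t",
                                   dtype={"chrom": str})
        tracks = rec.CovariateTracks.from_tracks(
            rec.read_track(cdir / "reptime.track.tsv"),
            rec.read_track(cdir / "coverage.track.tsv"),
            rec.read_track(cdir / "refclass.track.tsv"))
        mappability = pd.read_csv(
            cdir / "mappability.bed", sep="\t", header=None,
            names=["chrom", "start", "end"], dtype={0: str})
        maf = read_maf(cdir / "snvs.maf.tsv")
        seg = pd.read_csv(cdir / "cnv.seg", sep="\t", dtype={"chrom": str})
        counts = pd.read_csv(cdir / "counts.tsv", sep="\t", index_col=0)
        samples = pd.read_csv(cdir / "samples.tsv", sep="\t",
                              keep_default_na=False)
        catalog = sig.SignatureCatalog.read(cdir / "signatures.catalog.tsv")
        chrom_lengths = (mappability.groupby("chrom")["end"].max()
                         .astype(int).to_dict())
        tumor_ids = sorted(samples["sample_id"])

        # ---- variant QC
        s = stage("variant_qc")
        s["n_input"] = len(maf)
        maf, rejections = filter_variant_frame(maf)
        s["n_pass"] = len(maf)
        s["rejections"] = rejections

        # ---- regions
        s = stage("regions")
        promoters = define_promoters(tss, chrom_lengths)
        s["n_promoters"] = len(promoters)
        s["n_interactions_input"] = len(interactions)
        kept = filter_interactions(interactions)
        s["n_interactions_kept"] = len(kept)
        frag_groups = kept.groupby(["fragment_id", "chrom", "start", "end"])
        fragments = [
            CREFragment(
                fragment_id=fid,
                interval=GenomicInterval(chrom, int(fs), int(fe)),
                target_genes=sorted(g["gene"].unique()),
                scores=dict(zip(g["gene"], g["score"])),
            )
            for (fid, chrom, fs, fe), g in frag_groups
        ]
        s["n_fragments"] = len(fragments)
        fragments = mappability_filter(fragments, mappability,
                                       th.mappability_min)
        s["n_fragments_mappable"] = len(fragments)

        # ---- recurrence (separate batches)
        s = stage("recurrence")
        results = {}
        for kind, regions in (("promoter", promoters), ("cre", fragments)):
            model = rec.fit_background(maf, tracks, regions, kind=kind,
                                       tumor_ids=tumor_ids)
            res = rec.run_recurrence(
                regions, maf, model, tracks, tumor_ids,
                n_perm=th.n_perm, seed=config.seed)
            res["kind"] = kind
            res["config_hash"] = chash
            res.to_csv(odir / f"recurrence_{kind}.tsv", sep="\t", index=False,
                       float_format="%.6g")
            results[kind] = res
            s[f"n_{kind}_tested"] = len(res)
            s[f"n_{kind}_significant"] = int((res["q"] < th.q_recurrence).sum())

        # ---- expression effects of SNVs
        s = stage("expression")
        gene_ivals = _gene_intervals(tss, config.gene_body_pad)
        region_lookup = {p.region_id: p for p in promoters}
        region_lookup.update({f.region_id: f for f in fragments})
        muts_prom = rec.assign_mutations(promoters, maf)
        muts_cre = rec.assign_mutations(fragments, maf)
        mutated_by_region = {
            rid: set(df["tumor_id"])
            for rid, df in {**muts_prom, **muts_cre}.items()
        }
        pairs = []
        sig_cres: dict[str, set] = {}
        for kind, res in results.items():
            hits = res.loc[res["q"] < th.q_recurrence, "region_id"]
            for rid in hits:
                regobj = region_lookup[rid]
                genes = ([regobj.gene_id] if kind == "promoter"
                         else regobj.target_genes)
                for g in genes:
                    if g in gene_ivals:
                        pairs.append((rid, regobj.interval, g, gene_ivals[g]))
                        if kind == "cre":
                            sig_cres.setdefault(g, set()).add(rid)
        siblings = {
            rid: {o: mutated_by_region.get(o, set())
                  for g in genes_of
                  for o in sig_cres.get(g, set()) if o != rid}
            for rid, _, gene, _ in pairs
            for genes_of in [[gene]]
        }
        expr = ExpressionMatrix(counts)
        de = de_pipeline(pairs, mutated_by_region, siblings, seg, expr)
        de_cols = ["region_id", "gene_id", "n_mutated", "n_unmutated",
                   "fold_change", "p", "q", "candidate", "config_hash"]
        de_df = pd.DataFrame([asdict(r) for r in de], columns=de_cols[:-2])
        de_df["candidate"] = [r.candidate for r in de]
        de_df["config_hash"] = chash
        de_df.to_csv(odir / "de.tsv", sep="\t", index=False,
                     float_format="%.6g")
        s["n_pairs_tested"] = len(de)
        s["n_candidates"] = int(sum(r.candidate for r in de))

        # ---- CNV and karyotype
        s = stage("cnv")
        calls = cnvmod.karyotype_table(seg, chrom_lengths, samples)
        kdf = pd.DataFrame([
            {"sample_id": k.sample_id, "hd": k.hd,
             "amplified": ";".join(sorted(k.amplified_chromosomes)),
             "translocations": ";".join(sorted(k.translocations)),
             "config_hash": chash}
            for k in calls])
        kdf.to_csv(odir / "karyotype.tsv", sep="\t", index=False)
        s["n_hd"] = int(kdf["hd"].sum())
        subgroup_members = {"HD": {k.sample_id for k in calls if k.hd}}
        for lab in config.subgroups:
            if lab == "HD":
                continue
            subgroup_members[lab] = {
                k.sample_id for k in calls if lab in k.translocations}
        burden = maf.groupby("tumor_id").size().reindex(
            tumor_ids, fill_value=0)
        s["burden_tests"] = wb = {}
        for row in st.wilcoxon_burden(burden, subgroup_members).itertuples(
                index=False):
            wb[row.subgroup] = row.p

        cnv_rows = []
        for rid, _, gene, give in pairs:
            regobj = region_lookup[rid]
            if not rid.startswith("cre:") or gene not in counts.index:
                continue
            cnv_rows.extend(cnvmod.cre_cnv_expression(
                regobj.interval, gene, give, seg, expr,
                min_group=th.min_cnv_group))
        cnv_de = cnvmod.cnv_de_table(cnv_rows)
        cnv_de.to_csv(odir / "cnv_de.tsv", sep="\t", index=False,
                      float_format="%.6g")
        s["n_cnv_de_tests"] = len(cnv_de)

        # ---- signatures and AID
        s = stage("signatures")
        exposures = {}
        for tid, grp in maf.groupby("tumor_id"):
            spectrum = sig.trinucleotide_spectrum(grp)
            if spectrum.sum() == 0:
                continue
            exposures[tid] = sig.refit_exposures(spectrum, catalog,
                                                 sample_id=tid)
        edf = pd.DataFrame({t: e.weights for t, e in exposures.items()}).T
        edf.index.name = "sample_id"
        edf["config_hash"] = chash
        edf.to_csv(odir / "exposures.tsv", sep="\t", float_format="%.6g")
        aid = sig.classify_aid(maf)
        aid_counts = aid.value_counts().to_dict()
        s["aid_labels"] = {k: int(v) for k, v in sorted(aid_counts.items())}
        s["n_samples_fit"] = len(exposures)

        # ---- subgroup scans of mutated regions
        s = stage("subgroup_scan")
        cohort = set(tumor_ids)
        scans = {}
        for r in de:
            feat = mutated_by_region.get(r.region_id, set())
            df = st.subgroup_scan(feat, subgroup_members, cohort)
            scans[r.region_id] = {
                row.subgroup: row.p for row in df.itertuples(index=False)}
        s["n_regions_scanned"] = len(scans)

        report["n_driver_candidates"] = report["stages"]["expression"][
            "n_candidates"]
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {current['name']!r}: {exc}") from exc

    with open(odir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report
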