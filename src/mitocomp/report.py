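"""End-to-end pipeline orchestration and report tables.

Every number in every report is recomputed from the input genomes by the
underlying operation; the report layer only formats (percentages rounded
half-up to 2 decimals, skews to 4). Reruns under an identical config produce
byte-identical TSV and Newick outputs.
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from . import composition, introns, phylo, rates, repeats
from .io_formats import read_fasta, read_genbank, read_newick
from .model import CORE_PCGS, PHYLO_PCGS, Mitogenome

log = logging.getLogger(__name__)


def percentage(part: float, whole: float, decimals: int = 2) -> str:
    """part/whole as a percentage string, rounded half-up."""
    if whole == 0:
        raise ZeroDivisionError("percentage of a zero total")
    q = Decimal(1).scaleb(-decimals)
    return str((Decimal(part) / Decimal(whole) * 100).quantize(q, ROUND_HALF_UP))


def fmt(x: float, decimals: int = 4) -> str:
    q = Decimal(1).scaleb(-decimals)
    return str(Decimal(repr(float(x))).quantize(q, ROUND_HALF_UP))


def overview_table(genomes: list[Mitogenome]) -> pd.DataFrame:
    """One row per species: length, GC%, skews, feature counts, intron share."""
    rows = []
    for g in genomes:
        st = composition.skew_stats(g.sequence)
        part = composition.region_partition(g)
        n_introns = len(g.features_of_kind("intron"))
        rows.append({
            "species": g.species_id,
            "length_bp": len(g.sequence),
            "gc_pct": percentage(st.gc_fraction, 1.0),
            "at_skew": fmt(st.at_skew, 4),
            "gc_skew": fmt(st.gc_skew, 4),
            "n_pcg": len(g.features_of_kind("PCG")),
            "n_trna": len(g.features_of_kind("tRNA")),
            "n_rrna": len(g.features_of_kind("rRNA")),
            "n_orf": len(g.features_of_kind("orf")),
            "n_introns": n_introns,
            "intron_nt": part["intron"],
            "intron_pct": percentage(part["intron"], len(g.sequence)),
        })
    return pd.DataFrame(rows).set_index("species")


def per_gene_composition(genomes: list[Mitogenome],
                         genes: tuple[str, ...] = CORE_PCGS) -> pd.DataFrame:
    """Per-gene per-species length, GC% and skews of the coding sequences."""
    rows = []
    for g in genomes:
        for gene in genes:
            try:
                cds = g.cds(gene)
            except KeyError:
                continue
            st = composition.skew_stats(cds)
            rows.append({"species": g.species_id, "gene": gene,
                         "length_bp": len(cds),
                         "gc_pct": percentage(st.gc_fraction, 1.0),
                         "at_skew": fmt(st.at_skew, 4),
                         "gc_skew": fmt(st.gc_skew, 4)})
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    genomes_dir: str
    reference_path: str | None = None
    tree_path: str | None = None              # None -> infer by NJ
    out_dir: str = "mitocomp_out"
    seed: int = 0
    bootstrap_reps: int = 200
    outgroup: str | None = None
    identity_threshold: float = 0.7
    orf_min_nt: int = 300
    gain_loss_mode: str = "dollo"
    run_phylo: bool = True
    run_repeats: bool = True

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ReportBundle:
    out_dir: Path
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)
    partial: bool = False
    errors: list[str] = field(default_factory=list)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_all(config: RunConfig) -> ReportBundle:
    """Execute composition → rates → repeats → introns → phylo and write
    every table as TSV plus a run manifest. Stage errors mark the bundle
    partial and skip dependent stages."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle = ReportBundle(out_dir=out)
    gdir = Path(config.genomes_dir)
    paths = sorted(gdir.glob("*.gbk")) + sorted(gdir.glob("*.gb"))
    genomes = [read_genbank(p) for p in paths]
    if not genomes:
        raise FileNotFoundError(f"no GenBank files in {gdir}")
    log.info("== composition: %d genomes", len(genomes))

    ov = overview_table(genomes)
    _write_tsv(ov, out / "overview.tsv")
    bundle.tables["overview"] = ov

    usage = composition.codon_usage(genomes)
    cu = pd.DataFrame({
        "codon": list(usage.counts),
        "count": list(usage.counts.values()),
        "freq_per_thousand": [fmt(v, 4) for v in usage.freq_per_thousand.values()],
        "rscu": [fmt(v, 4) for v in usage.rscu.values()],
    })
    _write_tsv(cu, out / "codon_usage.tsv", index=False)
    bundle.tables["codon_usage"] = cu

    pg = per_gene_composition(genomes)
    _write_tsv(pg, out / "per_gene_composition.tsv", index=False)
    bundle.tables["per_gene_composition"] = pg

    corr_df = pd.DataFrame()
    if len(genomes) >= 3:
        pts = [(len(g.features_of_kind("intron")), len(g.sequence))
               for g in genomes]
        try:
            r, p_r, rho, p_rho = composition.intron_size_correlation(pts)
            corr_df = pd.DataFrame([{
                "pearson_r": fmt(r, 4), "pearson_p": fmt(p_r, 6),
                "spearman_rho": fmt(rho, 4), "spearman_p": fmt(p_rho, 6)}])
        except composition.DomainError as exc:
            bundle.errors.append(f"correlation: {exc}")
    if not corr_df.empty:
        _write_tsv(corr_df, out / "intron_size_correlation.tsv", index=False)
        bundle.tables["intron_size_correlation"] = corr_df

    log.info("== evolutionary rates")
    try:
        _, _, rate_table = rates.gene_rates(genomes)
        rt = rate_table.map(lambda v: fmt(v, 6) if pd.notna(v) and
                            not isinstance(v, int) else v)
        _write_tsv(rt, out / "rates.tsv")
        bundle.tables["rates"] = rt
    except Exception as exc:  # stage isolation by contract
        bundle.partial = True
        bundle.errors.append(f"rates: {exc}")

    if config.run_repeats:
        log.info("== repeats")
        rep_rows = []
        for g in genomes:
            for r in repeats.find_ssrs(g):
                rep_rows.append({
                    "species": g.species_id, "class": "SSR",
                    "motif_or_period": r.motif, "copies": r.copies,
                    "start": r.start + 1, "end": r.end, "orientation": "",
                    "mismatches": 0,
                    "region": repeats.repeat_region_class(g, r.start, r.end)})
            for r in repeats.find_dispersed(g):
                rep_rows.append({
                    "species": g.species_id, "class": "dispersed",
                    "motif_or_period": r.length, "copies": 2,
                    "start": r.start_a + 1, "end": r.start_a + r.length,
                    "orientation": r.orientation, "mismatches": r.mismatches,
                    "region": repeats.repeat_region_class(
                        g, r.start_a, r.start_a + r.length)})
            for r in repeats.find_tandem(g):
                rep_rows.append({
                    "species": g.species_id, "class": "tandem",
                    "motif_or_period": r.period, "copies": r.copies,
                    "start": r.start + 1, "end": r.end, "orientation": "",
                    "mismatches": 0,
                    "region": repeats.repeat_region_class(g, r.start, r.end)})
        rp = pd.DataFrame(rep_rows)
        _write_tsv(rp, out / "repeats.tsv", index=False)
        bundle.tables["repeats"] = rp

    log.info("== introns")
    census = introns.intron_census(genomes)
    _write_tsv(census, out / "intron_census.tsv")
    bundle.tables["intron_census"] = census

    matrix_df = pd.DataFrame()
    events_df = pd.DataFrame()
    if config.reference_path:
        refs = dict(read_fasta(config.reference_path))
        assignments = []
        for g in genomes:
            for gene in CORE_PCGS:
                if gene not in refs:
                    continue
                try:
                    g.gene(gene)
                except KeyError:
                    continue
                assignments.extend(introns.assign_pcl(g, gene, refs[gene]))
        matrix = introns.cluster_orthologs(
            assignments, identity_threshold=config.identity_threshold,
            species=[g.species_id for g in genomes])
        matrix_df = matrix.to_frame()
        _write_tsv(matrix_df, out / "pcl_matrix.tsv")
        bundle.tables["pcl_matrix"] = matrix_df
        adf = pd.DataFrame([{
            "species": a.species, "gene": a.gene, "pcl": a.label,
            "confident": int(a.confident),
            "identity": fmt(a.alignment_identity, 4)} for a in assignments])
        _write_tsv(adf, out / "pcl_assignments.tsv", index=False)
        bundle.tables["pcl_assignments"] = adf
        if config.tree_path:
            tree = read_newick(config.tree_path)
            ev = introns.gain_loss(matrix, tree, mode=config.gain_loss_mode)
            ev_rows = []
            for col in sorted(ev.gains):
                for b in ev.gains[col]:
                    ev_rows.append({"pcl": col, "event": "gain",
                                    "branch": "|".join(b)})
                for b in ev.losses.get(col, ()):
                    ev_rows.append({"pcl": col, "event": "loss",
                                    "branch": "|".join(b)})
            events_df = pd.DataFrame(ev_rows)
            _write_tsv(events_df, out / "gain_loss_events.tsv", index=False)
            bundle.tables["gain_loss_events"] = events_df

    if config.run_phylo:
        log.info("== phylogeny")
        try:
            per_gene = []
            for gene in PHYLO_PCGS:
                cds_map = {g.species_id: g.cds(gene) for g in genomes}
                per_gene.append((gene, rates.codon_align(cds_map)))
            supermatrix, _ = phylo.concatenate(per_gene)
            st = phylo.bootstrap(supermatrix, n_reps=config.bootstrap_reps,
                                 seed=config.seed)
            if config.outgroup:
                phylo.root_at_outgroup(st.tree, config.outgroup)
            with open(out / "tree.nwk", "w") as fh:
                fh.write(st.newick())
        except Exception as exc:
            bundle.partial = True
            bundle.errors.append(f"phylo: {exc}")

    manifest = {
        "seed": config.seed,
        "n_genomes": len(genomes),
        "species": [g.species_id for g in genomes],
        "parameters": {
            "bootstrap_reps": config.bootstrap_reps,
            "identity_threshold": config.identity_threshold,
            "orf_min_nt": config.orf_min_nt,
            "gain_loss_mode": config.gain_loss_mode,
        },
        "partial": bundle.partial,
        "errors": bundle.errors,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    if bundle.partial:
        print("pipeline completed with errors: " + "; ".join(bundle.errors),
              file=sys.stderr)
    return bundle
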