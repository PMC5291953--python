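"""End-to-end orchestration: simulate -> extract -> assemble -> isoforms ->
stats, with per-stage loss accounting and a reproducibility manifest."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import yaml

from . import __version__
from . import assemble as asm
from . import extract as ext
from . import io as iio
from . import isoforms as iso
from . import simulate as sim
from . import stats as st
from .errors import ConfigError
from .types import Transcript, ValidRead

SIM_DEFAULTS = {f.name: f.default if f.default is not dataclasses.MISSING
                else tuple(f.default_factory())  # pragma: no cover
                for f in dataclasses.fields(sim.SimConfig)}

DEFAULTS = {
    "seed": 1,
    "simulate": {k: v for k, v in SIM_DEFAULTS.items() if k != "seed"},
    "extract": {"max_mismatches": 2, "proximity": 10, "polya_run": 10},
    "assemble": {"gap_lt": 40},
    "isoforms": {"link_dist": 5, "junction_tol": 1, "level": "conservative"},
    "stats": {"premature_threshold": 0.15, "position_tol": 1},
}

_RANGES = {
    ("extract", "max_mismatches"): (0, 5),
    ("extract", "proximity"): (0, 100),
    ("extract", "polya_run"): (1, 100),
    ("assemble", "gap_lt"): (1, 1000),
    ("isoforms", "link_dist"): (0, 1000),
    ("isoforms", "junction_tol"): (0, 100),
    ("stats", "premature_threshold"): (0.0, 1.0),
    ("stats", "position_tol"): (0, 100),
}


def validate_config(source=None) -> dict:
    """Normalize a config mapping or YAML file against the schema.

    Unknown keys and out-of-range values are reported collectively.
    Defaults: link_dist=5, junction_tol=1, gap_lt=40, polyA run=10,
    adapter mismatches=2, proximity=10.
    """
    if source is None:
        raw = {}
    elif isinstance(source, dict):
        raw = source
    else:
        path = Path(source)
        if not path.exists():
            raise ConfigError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config must be a mapping")
    errors = []
    cfg = {"seed": DEFAULTS["seed"]}
    if "seed" in raw:
        try:
            cfg["seed"] = int(raw["seed"])
        except (TypeError, ValueError):
            errors.append("seed must be an integer")
    for section, defaults in DEFAULTS.items():
        if section == "seed":
            continue
        cfg[section] = dict(defaults)
        user = raw.get(section, {})
        if not isinstance(user, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        for key, val in user.items():
            if key not in defaults:
                errors.append(f"unknown key {section}.{key}")
                continue
            if isinstance(defaults[key], tuple):
                try:
                    val = tuple(int(v) for v in val)
                except (TypeError, ValueError):
                    errors.append(f"{section}.{key} must be a 2-range")
                    continue
            cfg[section][key] = val
        for (sec, key), (lo, hi) in _RANGES.items():
            if sec == section and key in cfg[section]:
                v = cfg[section][key]
                if not isinstance(v, (int, float)) or not lo <= v <= hi:
                    errors.append(f"{section}.{key}={v} outside [{lo}, {hi}]")
    for key in raw:
        if key not in DEFAULTS:
            errors.append(f"unknown section {key!r}")
    if not errors:
        try:
            sim_config(cfg)
        except ConfigError as exc:
            errors.append(str(exc))
    if errors:
        raise ConfigError("; ".join(errors))
    return cfg


def sim_config(cfg: dict) -> sim.SimConfig:
    kwargs = dict(cfg["simulate"])
    for key in ("exon_count", "exon_length", "intron_length", "ercc_length",
                "concatemer_arity"):
        kwargs[key] = tuple(kwargs[key])
    if kwargs.get("isoform_weights") is not None:
        kwargs["isoform_weights"] = tuple(kwargs["isoform_weights"])
    return sim.SimConfig(seed=cfg["seed"], **kwargs).validate()


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=list).encode()).hexdigest()[:16]


# ----------------------------------------------------------- stage io

VALID_READ_COLS = ["read_id", "subread_index", "barcode", "umi", "case",
                   "has_polya", "g_run", "first8", "template_len"]


def write_valid_reads(path, reads: list[ValidRead]):
    iio.write_tsv(path, VALID_READ_COLS, [
        (r.read_id, r.subread_index, r.barcode, r.umi, r.case,
         int(r.has_polya), r.g_run, r.first8, len(r.template_seq))
        for r in reads
    ])


def read_valid_reads(path) -> list[ValidRead]:
    out = []
    for row in iio.read_tsv(path):
        out.append(ValidRead(
            read_id=row["read_id"], subread_index=int(row["subread_index"]),
            barcode=row["barcode"], umi=row["umi"], case=int(row["case"]),
            template_seq=row["first8"], has_polya=bool(int(row["has_polya"])),
            g_run=int(row["g_run"]),
        ))
    return out


def write_transcripts(bed_path, tsv_path, transcripts: list[Transcript]):
    iio.write_bed12(bed_path, [
        iio.blocks_to_bed12(t.chrom, t.transcript_id, t.strand, t.blocks,
                            score=t.read_support)
        for t in transcripts
    ])
    iio.write_tsv(tsv_path,
                  ["transcript_id", "cell_barcode", "gene_id", "umi",
                   "read_support", "has_polya", "covers_first_exon", "is_ercc"],
                  [(t.transcript_id, t.cell_barcode, t.gene_id, t.umi,
                    t.read_support, int(t.has_polya),
                    "" if t.covers_first_exon is None
                    else int(t.covers_first_exon), int(t.is_ercc))
                   for t in transcripts])


def read_transcripts(bed_path, tsv_path) -> list[Transcript]:
    side = {row["transcript_id"]: row for row in iio.read_tsv(tsv_path)}
    out = []
    for rec in iio.read_bed12(bed_path):
        row = side[rec.name]
        out.append(Transcript(
            cell_barcode=row["cell_barcode"], gene_id=row["gene_id"],
            umi=row["umi"], chrom=rec.chrom, strand=rec.strand,
            blocks=rec.blocks, read_support=int(row["read_support"]),
            has_polya=bool(int(row["has_polya"])),
            covers_first_exon=(None if row["covers_first_exon"] == ""
                               else bool(int(row["covers_first_exon"]))),
            is_ercc=bool(int(row["is_ercc"])),
        ))
    return out


def write_isoforms(path, isoforms):
    iio.write_tsv(path,
                  ["gene_id", "level", "key", "n_transcripts", "transcript_ids"],
                  [(i.gene_id, i.level, repr(i.key), i.n_transcripts,
                    ",".join(i.transcript_ids)) for i in isoforms])


# ----------------------------------------------------------- pipeline

def run_pipeline(cfg: dict | None = None, outdir=None) -> dict:
    """Run every stage under one config; returns the run manifest.

    The manifest records per-stage input/output counts and rejection
    reasons (counts are non-increasing through the filtering stages) and
    regenerates identically for a fixed seed and config.
    """
    cfg = validate_config(cfg) if not _is_validated(cfg) else cfg
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "tool": "isoscope", "version": __version__,
        "seed": cfg["seed"], "config_hash": config_hash(cfg),
        "stages": {},
    }

    # --- simulate
    scfg = sim_config(cfg)
    simres = sim.simulate(scfg, outdir=outdir / "simulate" if outdir else None)
    n_molecules = len(simres.molecules)
    manifest["stages"]["simulate"] = {
        "n_genes": len(simres.models), "n_ercc": len(simres.ercc_models),
        "n_molecules": n_molecules, "n_fastq_records": len(simres.fastq),
        "n_subreads": len(simres.read_truth),
    }

    # --- extract
    ecfg = cfg["extract"]
    exres = ext.extract_reads(simres.fastq, max_mm=ecfg["max_mismatches"],
                              proximity=ecfg["proximity"])
    manifest["stages"]["extract"] = {
        "n_subreads_in": len(exres.valid_reads) + len(exres.rejections),
        "n_valid_reads": len(exres.valid_reads),
        "rejections": dict(exres.rejection_counts),
    }
    if outdir is not None:
        (outdir / "extract").mkdir(exist_ok=True)
        write_valid_reads(outdir / "extract" / "valid_reads.tsv",
                          exres.valid_reads)

    # --- assemble
    vr_by_name = {r.name: r for r in exres.valid_reads}
    aligned = asm.load_alignments(simres.alignments, vr_by_name,
                                  gap_lt=cfg["assemble"]["gap_lt"])
    all_models = {**simres.models, **simres.ercc_models}
    asm.annotate_genes(aligned, all_models)
    assigned = [r for r in aligned if r.gene_id is not None]
    mlog = asm.UmiMergeLog()
    transcripts = asm.build_transcripts(assigned, mlog)
    full_length = asm.filter_full_length(transcripts, simres.models)
    manifest["stages"]["assemble"] = {
        "n_aligned": len(aligned), "n_gene_assigned": len(assigned),
        "n_unassigned": len(aligned) - len(assigned),
        "n_transcripts": len(transcripts),
        "n_full_length": len(full_length),
        "umi_merge": dataclasses.asdict(mlog),
        "singleton_umi_fraction": (
            sum(t.read_support == 1 for t in transcripts) / len(transcripts)
            if transcripts else float("nan")),
    }
    if outdir is not None:
        (outdir / "assemble").mkdir(exist_ok=True)
        write_transcripts(outdir / "assemble" / "transcripts.bed",
                          outdir / "assemble" / "transcripts.tsv", transcripts)

    # --- isoforms
    icfg = cfg["isoforms"]
    levels = {
        "full": iso.build_isoforms(transcripts, simres.models, "full",
                                   icfg["link_dist"], icfg["junction_tol"]),
        "conservative": iso.build_isoforms(full_length, simres.models,
                                           "conservative", icfg["link_dist"],
                                           icfg["junction_tol"]),
        "cassette": iso.build_isoforms(full_length, simres.models, "cassette"),
    }
    manifest["stages"]["isoforms"] = {
        f"n_{lvl}": len(v) for lvl, v in levels.items()
    }
    manifest["stages"]["isoforms"]["transcripts_per_conservative"] = (
        sum(i.n_transcripts for i in levels["conservative"])
        / len(levels["conservative"]) if levels["conservative"] else float("nan"))
    if outdir is not None:
        (outdir / "isoforms").mkdir(exist_ok=True)
        for lvl, v in levels.items():
            write_isoforms(outdir / "isoforms" / f"isoforms_{lvl}.tsv", v)

    # --- stats
    coding_by_gene = {g: m.cds_intervals for g, m in simres.models.items()}
    records = st.structure_offsets(transcripts, simres.models, coding_by_gene)
    umi_groups: dict[tuple, list] = {}
    for r in assigned:
        umi_groups.setdefault((r.read.barcode, r.gene_id, r.read.umi),
                              []).append(r)
    umi_records = st.within_umi_offsets(umi_groups)
    ercc_records, ercc_frac = st.ercc_end_offsets(transcripts,
                                                  simres.ercc_models)
    rels, premature = st.relative_end_positions(
        transcripts, simres.models,
        premature_threshold=cfg["stats"]["premature_threshold"])
    events = st.count_events(full_length, simres.models,
                             link_dist=icfg["link_dist"],
                             position_tol=cfg["stats"]["position_tol"])
    mix = st.event_mix(events)
    celltype_of = {b: b for b in simres.cell_barcodes}
    sharing = (st.isoform_sharing(levels["conservative"], celltype_of)
               if len(celltype_of) >= 2 else None)
    majors = st.major_isoform_fraction(levels["conservative"])
    cvn = st.coding_vs_noncoding_test(records)
    manifest["stages"]["stats"] = {
        "n_offset_records": len(records),
        "within_umi": {
            "n_records": len(umi_records),
            "fraction_within_1bp": (
                sum(abs(r.offset) <= 1 for r in umi_records) / len(umi_records)
                if umi_records else float("nan")),
        },
        "ercc_fraction_within": {f"{s}_{k}bp": v
                                 for (s, k), v in ercc_frac.items()},
        "premature_3p_fraction": premature,
        "event_mix_pct": mix,
        "coding_vs_noncoding_p": cvn,
        "sharing": (None if sharing is None else {
            "frac_any_two": sharing.frac_any_two,
            "frac_all_shared": sharing.frac_all_shared,
            "n_isoforms": sharing.n_isoforms,
        }),
        "mean_major_isoform_fraction": (
            float(sum(majors.values()) / len(majors)) if majors
            else float("nan")),
    }
    if outdir is not None:
        stats_dir = outdir / "stats"
        stats_dir.mkdir(exist_ok=True)
        iio.write_tsv(stats_dir / "offsets.tsv",
                      ["site", "coding", "offset", "context"],
                      [(r.site, r.coding, r.offset, repr(r.context))
                       for r in records])
        iio.write_tsv(stats_dir / "events.tsv",
                      ["cell", "gene_id", "tss", "tts", "position", "cassette"],
                      [(e.cell, e.gene_id, e.n_tss, e.n_tts, e.n_position,
                        e.n_cassette) for e in events])
        _write_report(stats_dir, manifest, records, ercc_records)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _is_validated(cfg) -> bool:
    return isinstance(cfg, dict) and set(DEFAULTS) <= set(cfg or {})


def _write_report(stats_dir: Path, manifest: dict, records, ercc_records):
    """Markdown report with the offset histograms and headline numbers."""
    lines = ["# isoscope run report", ""]
    stages = manifest["stages"]
    lines += ["## Per-stage accounting", "```",
              json.dumps(stages, indent=2, sort_keys=True), "```", ""]
    for title, recs in (("Endogenous", records), ("ERCC", ercc_records)):
        lines.append(f"## {title} offset histograms")
        for site in ("end5", "end3", "junction_start", "junction_end"):
            offs = [r.offset for r in recs if r.site == site]
            if not offs:
                continue
            hist = st.offset_histogram(offs)
            lines.append(f"### {site} (n={len(offs)})")
            lines.append("| " + " | ".join(hist) + " |")
            lines.append("|" + "---|" * len(hist))
            lines.append("| " + " | ".join(str(v) for v in hist.values()) + " |")
        lines.append("")
    (stats_dir / "report.md").write_text("\n".join(lines))
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:  # plotting is optional
        return
    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    for ax, (title, recs) in zip(axes, (("endogenous", records),
                                        ("ERCC ends", ercc_records))):
        for site in ("end5", "end3"):
            offs = [r.offset for r in recs if r.site == site]
            if offs:
                hist = st.offset_histogram(offs)
                ax.bar(range(len(hist)), list(hist.values()), alpha=0.5,
                       label=site)
        ax.set_xticks(range(len(st.OFFSET_BIN_LABELS)))
        ax.set_xticklabels(st.OFFSET_BIN_LABELS, rotation=90, fontsize=7)
        ax.set_title(title)
        ax.legend()
    fig.tight_layout()
    fig.savefig(stats_dir / "offsets.png", dpi=100)
    plt.close(fig)
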