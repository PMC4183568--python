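"""File formats: FASTA amplicons, peak-table CSVs, TSV tables, datasets.

Peak tables use the flattened GeneMapper-export dialect
(``sample_id,dye,size_bp,height,area``). A simulated study round-trips
through a plain-text directory layout so the CLI stages can hand files to
each other.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .community import CommunityTemplate, build_predicted_profile, templates_to_frame
from .digest import GenotypeRecord, TRFTable, predict_trf_table
from .processing import PEAK_COLUMNS, validate_peak_table

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_peak_table",
    "write_peak_table",
    "write_trf_table",
    "read_templates",
    "write_templates",
    "write_study_dataset",
    "read_study_dataset",
    "file_sha256",
]


def read_fasta(
    path, dye_end_map: Mapping[str, str] | None = None
) -> list[GenotypeRecord]:
    """Read a (possibly wrapped, multi-record) FASTA of amplicon genotypes.

    IUPAC ambiguity codes are accepted here; digestion rejects them later
    with an explicit error. All records receive the same dye-to-end map
    (default: HEX on the left end, FAM on the right).
    """
    dye_end_map = dict(dye_end_map or {"HEX": "left", "FAM": "right"})
    records = [
        GenotypeRecord(id=rec.id, sequence=str(rec.seq), dye_end_map=dict(dye_end_map))
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: Sequence[GenotypeRecord], path) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records],
        str(path),
        "fasta",
    )


def read_peak_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    return validate_peak_table(table)


def write_peak_table(table: pd.DataFrame, path) -> None:
    validate_peak_table(table)
    table.to_csv(path, index=False, columns=PEAK_COLUMNS)


def write_trf_table(table: TRFTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_templates(templates, path) -> None:
    templates_to_frame(templates).to_csv(path, sep="\t", index=False)


def read_templates(path) -> list[CommunityTemplate]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for name, grp in df.groupby("template_name", sort=False):
        out.append(
            CommunityTemplate(
                str(name), dict(zip(grp["genotype_id"], grp["proportion"]))
            )
        )
    return out


def file_sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ----------------------------------------------------------------------
# Study-dataset directory layout:
#   genotypes.fasta            amplicon sequences
#   trf_table.tsv              predicted complete + pseudo TRFs
#   templates.tsv              nominal 9-template design
#   replicate_templates.tsv    actual pipetted compositions (27)
#   manifest.tsv               sample_id / template / replicate / tech_rep
#   peaks_<enzyme>.csv         all technical replicates, one file per channel
#   config.yaml                provenance snapshot
# ----------------------------------------------------------------------


def write_study_dataset(dataset, outdir) -> Path:
    """Write a simulated study to a plain-text directory (see layout above)."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(dataset.records, out / "genotypes.fasta")
    write_trf_table(dataset.trf_table, out / "trf_table.tsv")
    write_templates(dataset.templates, out / "templates.tsv")
    rep_rows = [
        {"template": t_name, "replicate": rep, "genotype_id": g, "proportion": p}
        for (t_name, rep), tmpl in dataset.replicate_templates.items()
        for g, p in tmpl.composition.items()
    ]
    pd.DataFrame(rep_rows).to_csv(out / "replicate_templates.tsv", sep="\t", index=False)
    dataset.manifest.to_csv(out / "manifest.tsv", sep="\t", index=False)
    for enz_name, table in dataset.peak_tables.items():
        write_peak_table(table, out / f"peaks_{enz_name}.csv")
    cfg = dataset.config
    snapshot = {
        "seed": cfg.seed,
        "n_genotypes": cfg.n_genotypes,
        "length_range": list(cfg.length_range),
        "gc_range": list(cfg.gc_range),
        "max_similarity": cfg.max_similarity,
        "min_trf_separation": cfg.min_trf_separation,
        "pair_deltas": list(cfg.pair_deltas),
        "n_replicates": cfg.n_replicates,
        "n_tech_reps": cfg.n_tech_reps,
        "total_area": cfg.total_area,
        "pipetting_cv": cfg.pipetting_cv,
        "bias": {
            k: getattr(cfg.bias, k)
            for k in (
                "drift_intercept",
                "drift_slope",
                "size_jitter_sd",
                "split_prob",
                "split_spread",
                "pseudo_rate",
                "area_noise_cv",
                "detection_floor",
            )
        },
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(snapshot, fh, sort_keys=True)
    return out


def read_study_dataset(indir):
    """Reconstruct a StudyDataset from a directory written by
    :func:`write_study_dataset`. Predicted profiles and the TRF table are
    recomputed from the sequences and compositions (they are derived data)."""
    from .simulate import BiasConfig, StudyConfig, StudyDataset

    src = Path(indir)
    with open(src / "config.yaml") as fh:
        snap = yaml.safe_load(fh)
    bias = BiasConfig(**snap.pop("bias"))
    snap["length_range"] = tuple(snap["length_range"])
    snap["gc_range"] = tuple(snap["gc_range"])
    snap["pair_deltas"] = tuple(snap["pair_deltas"])
    config = StudyConfig(bias=bias, **snap)
    records = read_fasta(src / "genotypes.fasta")
    trf_table = predict_trf_table(records)
    templates = read_templates(src / "templates.tsv")
    rep_df = pd.read_csv(src / "replicate_templates.tsv", sep="\t")
    replicate_templates = {}
    for (t_name, rep), grp in rep_df.groupby(["template", "replicate"], sort=False):
        replicate_templates[(str(t_name), int(rep))] = CommunityTemplate(
            f"{t_name}.r{rep}", dict(zip(grp["genotype_id"], grp["proportion"]))
        )
    manifest = pd.read_csv(src / "manifest.tsv", sep="\t")
    peak_tables = {
        p.stem.removeprefix("peaks_"): read_peak_table(p)
        for p in sorted(src.glob("peaks_*.csv"))
    }
    predicted_profiles = {
        (t_name, rep, enz): build_predicted_profile(tmpl, trf_table, enz)
        for (t_name, rep), tmpl in replicate_templates.items()
        for enz in peak_tables
    }
    return StudyDataset(
        config=config,
        records=records,
        trf_table=trf_table,
        templates=templates,
        replicate_templates=replicate_templates,
        predicted_profiles=predicted_profiles,
        peak_tables=peak_tables,
        manifest=manifest,
    )
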