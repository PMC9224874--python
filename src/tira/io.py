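"""File dialects.

Plain-text dialects used throughout:

* dosage TSV — header ``sample_id`` then variant ids, one row per sample,
  missing = ``NA``; variant sidecar TSV with id, chrom, pos, ref, alt.
* minimal VCF 4.2 — biallelic records with ``GT`` (and optional ``DS``).
* clinical CSV — cohort schema of :mod:`tira.containers`.
* weight tables — PredictDB SQLite (tables ``weights`` and ``extra``) or a
  TSV twin of ``weights`` for fixtures.
"""

from __future__ import annotations

import sqlite3
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import VARIANT_COLUMNS, GenotypeMatrix, WeightDB, validate_clinical
from .errors import DataError

# ---------------------------------------------------------------- dosage TSV


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> Path:
    """Write dosages + variant sidecar (``<path>`` and ``<stem>.variants.tsv``)."""
    path = Path(path)
    out = g.dosages.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", na_rep="NA", float_format="%.17g")
    side = g.variants.copy()
    side.index.name = "id"
    side.to_csv(_sidecar_path(path), sep="\t")
    return path


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".variants.tsv") if path.suffix else path.with_name(path.name + ".variants.tsv")


def read_dosage_tsv(path: str | Path, samples=None) -> GenotypeMatrix:
    """Read a dosage TSV and its variant sidecar.

    ``samples`` optionally realigns rows by id (the order on disk is
    otherwise preserved).
    """
    path = Path(path)
    d = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
    side = _sidecar_path(path)
    if not side.exists():
        raise DataError(f"variant sidecar not found: {side}")
    v = pd.read_csv(side, sep="\t", index_col="id", dtype={"chrom": str, "ref": str, "alt": str})
    g = GenotypeMatrix(d.astype(float), v)
    if samples is not None:
        g = g.reindex_samples(list(samples))
    return g


# ----------------------------------------------------------------------- VCF


def write_vcf(g: GenotypeMatrix, path: str | Path, dosage_field: bool = False) -> Path:
    """Minimal VCF 4.2 writer: biallelic records, GT (and optional DS).

    Hard-call dosages map to 0/0, 0/1, 1/1; non-integral dosages require
    ``dosage_field`` and are written as ``./.`` with a DS value.
    """
    path = Path(path)
    samples = g.sample_ids
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(g.variants["chrom"].astype(str)):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if dosage_field:
            fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        fmt = "GT:DS" if dosage_field else "GT"
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1"}
        for vid, meta in g.variants.iterrows():
            fields = [str(meta["chrom"]), str(int(meta["pos"])), str(vid), str(meta["ref"]), str(meta["alt"]), ".", "PASS", ".", fmt]
            col = g.dosages[vid]
            for s in samples:
                d = col.loc[s]
                if np.isnan(d):
                    cell = "./." + (":." if dosage_field else "")
                elif float(d).is_integer():
                    cell = gt_map[int(d)] + (f":{d:g}" if dosage_field else "")
                elif dosage_field:
                    cell = f"./.:{d:.17g}"
                else:
                    raise DataError(f"non-integral dosage {d} needs dosage_field=True")
                fields.append(cell)
            fh.write("\t".join(fields) + "\n")
    return path


def read_vcf(path: str | Path, samples=None) -> GenotypeMatrix:
    """Read a (plain-text) VCF into a GenotypeMatrix via pysam.

    DS takes precedence over GT when present; missing calls become NaN.
    """
    import pysam

    vf = pysam.VariantFile(str(path))
    file_samples = list(vf.header.samples)
    ids, rows, meta = [], [], []
    for rec in vf:
        if rec.alts is None or len(rec.alts) != 1:
            raise DataError(f"record {rec.id or rec.pos} is not biallelic")
        vid = rec.id or f"{rec.chrom}:{rec.pos}:{rec.ref}:{rec.alts[0]}"
        dos = np.full(len(file_samples), np.nan)
        for i, s in enumerate(file_samples):
            sample = rec.samples[s]
            if "DS" in sample and sample.get("DS") is not None:
                dos[i] = float(sample["DS"])
            else:
                gt = sample.get("GT")
                if gt is not None and None not in gt:
                    dos[i] = float(sum(gt))
        ids.append(vid)
        rows.append(dos)
        meta.append((rec.chrom, rec.pos, rec.ref, rec.alts[0]))
    d = pd.DataFrame(
        np.column_stack(rows) if rows else np.empty((len(file_samples), 0)),
        index=pd.Index(file_samples, name="sample_id"),
        columns=ids,
    )
    v = pd.DataFrame(meta, index=pd.Index(ids, name="id"), columns=VARIANT_COLUMNS)
    g = GenotypeMatrix(d, v)
    if samples is not None:
        g = g.reindex_samples(list(samples))
    return g


def read_genotypes(path: str | Path, samples=None) -> GenotypeMatrix:
    """Dispatch on extension: .vcf -> VCF reader, otherwise dosage TSV."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_vcf(path, samples=samples)
    return read_dosage_tsv(path, samples=samples)


# ------------------------------------------------------------- clinical CSV


def write_clinical_csv(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    out = df.copy()
    out.index.name = "sample_id"
    out.to_csv(path)
    return path


def read_clinical_csv(path: str | Path, require_label: bool = True) -> pd.DataFrame:
    df = pd.read_csv(path, index_col="sample_id")
    return validate_clinical(df, require_label=require_label)


# ------------------------------------------------------------ weight tables

_TSV_COLUMNS = {"rsid": "variant_id", "gene": "gene", "weight": "weight", "ref_allele": "non_effect_allele", "eff_allele": "effect_allele"}


def write_weights_tsv(db: WeightDB, path: str | Path) -> Path:
    path = Path(path)
    out = db.weights.rename(columns={v: k for k, v in _TSV_COLUMNS.items()})
    out[list(_TSV_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.17g")
    return path


def write_weights_sqlite(db: WeightDB, path: str | Path) -> Path:
    """Write the PredictDB SQLite dialect (tables ``weights`` and ``extra``)."""
    path = Path(path)
    con = sqlite3.connect(path)
    try:
        w = db.weights.rename(columns={v: k for k, v in _TSV_COLUMNS.items()})[list(_TSV_COLUMNS)]
        w.to_sql("weights", con, index=False, if_exists="replace")
        extra = (
            db.weights.groupby("gene", sort=False)
            .size()
            .rename("n.snps.in.model")
            .reset_index()
            .assign(genename=lambda t: t["gene"], **{"pred.perf.R2": np.nan})
        )
        extra[["gene", "genename", "n.snps.in.model", "pred.perf.R2"]].to_sql("extra", con, index=False, if_exists="replace")
        con.commit()
    finally:
        con.close()
    return path


def load_weight_db(path: str | Path, tissue: str | None = None) -> WeightDB:
    """Load a weight set from PredictDB SQLite or its TSV twin.

    The tissue name defaults to the file stem.  Malformed schemas and
    duplicate (gene, variant) rows raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise DataError(f"weight db not found: {path}")
    tissue = tissue or path.stem
    if _is_sqlite(path):
        con = sqlite3.connect(path)
        try:
            w = pd.read_sql_query("SELECT rsid, gene, weight, ref_allele, eff_allele FROM weights", con)
        except Exception as exc:  # pragma: no cover - driver message varies
            raise DataError(f"malformed PredictDB file {path}: {exc}") from exc
        finally:
            con.close()
    else:
        w = pd.read_csv(path, sep="\t")
        missing = [c for c in _TSV_COLUMNS if c not in w.columns]
        if missing:
            raise DataError(f"weight TSV lacks columns: {missing}")
    w = w.rename(columns=_TSV_COLUMNS)
    return WeightDB(w[["gene", "variant_id", "effect_allele", "non_effect_allele", "weight"]], tissue=tissue)


def _is_sqlite(path: Path) -> bool:
    with open(path, "rb") as fh:
        return fh.read(16) == b"SQLite format 3\x00"


# ------------------------------------------------------------------- labels


def read_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV/CSV (sample_id, label with NDR/DR or 0/1)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col="sample_id")
    if "label" not in df.columns:
        raise DataError("labels file needs a 'label' column")
    return df["label"]
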