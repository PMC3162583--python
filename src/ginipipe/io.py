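"""Readers and writers for the pipeline's file interfaces.

All tabular formats are tab-delimited text; generated files carry ``#``
header comments recording the config hash and seed for provenance.  FASTA
goes through Biopython (60-column wrapping); dendrograms are written as
Newick strings.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .simulate import ArraySample
from .target_delta import VariantRecord

ARRAY_COLUMNS = [
    "ProbeName",
    "GeneName",
    "Band",
    "gMeanSignal",
    "rMeanSignal",
    "gBGMedianSignal",
    "rBGMedianSignal",
]


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serialisable configuration."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def _header_comment(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_tsv(df: pd.DataFrame, path, meta: dict | None = None, index: bool = False) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header_comment(meta))
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path, **kwargs) -> pd.DataFrame:
    # only empty fields are missing; word tokens like "null" are data here
    kwargs.setdefault("keep_default_na", False)
    kwargs.setdefault("na_values", [""])
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_array_sample(sample: ArraySample, path, meta: dict | None = None) -> None:
    info = {
        "sample_id": sample.sample_id,
        "family_id": sample.family_id,
        "status": "affected" if sample.affected else "healthy",
    }
    info.update(meta or {})
    write_tsv(sample.records[ARRAY_COLUMNS], path, meta=info)


def read_array_sample(path) -> ArraySample:
    path = Path(path)
    info = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            info[key.strip()] = value.strip()
    records = read_tsv(path)
    missing = [c for c in ARRAY_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"{path}: missing array columns {missing}")
    return ArraySample(
        sample_id=info.get("sample_id", path.stem),
        family_id=info.get("family_id", ""),
        affected=info.get("status", "") == "affected",
        records=records,
    )


def write_sample_sheet(sheet: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_tsv(sheet[["sample_id", "family_id", "status"]], path, meta=meta)


def read_sample_sheet(path, require_pairs: bool = False) -> pd.DataFrame:
    sheet = read_tsv(path)
    required = {"sample_id", "family_id", "status"}
    if not required <= set(sheet.columns):
        raise ValueError(f"sample sheet needs columns {sorted(required)}")
    if sheet["sample_id"].duplicated().any():
        dup = sheet.loc[sheet["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in sample sheet")
    bad = set(sheet["status"]) - {"affected", "healthy"}
    if bad:
        raise ValueError(f"unknown status values {sorted(bad)}")
    if require_pairs:
        for fam, sub in sheet.groupby("family_id"):
            statuses = set(sub["status"])
            if statuses != {"affected", "healthy"}:
                raise ValueError(
                    f"family {fam!r} lacks an affected/healthy pair for a paired stage"
                )
    return sheet


def write_expression_matrix(
    values: pd.DataFrame, path, meta: dict | None = None, feature_col: str = "feature_id"
) -> None:
    out = values.copy()
    out.index.name = feature_col
    write_tsv(out.reset_index(), path, meta=meta)


def read_expression_matrix(path, feature_col: str = "feature_id") -> pd.DataFrame:
    df = read_tsv(path)
    if feature_col not in df.columns:
        raise ValueError(f"expression matrix needs a {feature_col!r} column")
    out = df.set_index(feature_col)
    out.index.name = None
    return out


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


VARIANT_COLUMNS = ["seq_id", "pos_1based", "ref", "alt", "label"]


def write_variant_table(variants, path, meta: dict | None = None) -> None:
    df = pd.DataFrame(
        [
            {"seq_id": v.seq_id, "pos_1based": v.pos, "ref": v.ref, "alt": v.alt, "label": v.label}
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    )
    write_tsv(df, path, meta=meta)


def read_variant_table(path, targets: dict[str, str] | None = None) -> list[VariantRecord]:
    """Parse variants, optionally validating reference alleles against targets."""
    df = read_tsv(path, dtype={"ref": str, "alt": str, "label": str})
    missing = [c for c in VARIANT_COLUMNS[:4] if c not in df.columns]
    if missing:
        raise ValueError(f"variant table missing columns {missing}")
    variants = []
    for i, row in df.iterrows():
        v = VariantRecord(
            seq_id=str(row["seq_id"]),
            pos=int(row["pos_1based"]),
            ref=str(row["ref"]),
            alt=str(row["alt"]),
            label="" if pd.isna(row.get("label", "")) else str(row.get("label", "")),
        )
        if targets is not None:
            if v.seq_id not in targets:
                raise ValueError(f"line {i + 2}: unknown target {v.seq_id!r}")
            seq = targets[v.seq_id]
            if v.pos > len(seq) or seq[v.pos - 1].upper() != v.ref.upper():
                raise ValueError(
                    f"line {i + 2}: reference mismatch at {v.seq_id}:{v.pos} "
                    f"(sequence has {seq[v.pos - 1].upper()!r}, table says {v.ref!r})"
                )
        variants.append(v)
    return variants


def write_counts_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    write_tsv(df[["group", "carriers", "total", "role"]], path, meta=meta)


def read_counts_table(path) -> pd.DataFrame:
    df = read_tsv(path)
    required = {"group", "carriers", "total", "role"}
    if not required <= set(df.columns):
        raise ValueError(f"counts table needs columns {sorted(required)}")
    if (df["carriers"] > df["total"]).any():
        bad = df.loc[df["carriers"] > df["total"], "group"].iloc[0]
        raise ValueError(f"group {bad!r}: carriers exceed total")
    return df


def write_newick(newick: str, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(newick + ("\n" if not newick.endswith("\n") else ""))


def write_sidecar(path, params: dict, seed, input_paths=()) -> None:
    """JSON sidecar recording parameters, seed and input file hashes."""
    hashes = {}
    for p in input_paths:
        p = Path(p)
        hashes[p.name] = hashlib.sha256(p.read_bytes()).hexdigest()[:16]
    payload = {"params": params, "seed": seed, "input_hashes": hashes}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
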