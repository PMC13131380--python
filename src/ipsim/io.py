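"""File interfaces: pedigree/phenotype CSV, BLUPF90-style SNP files, YAML config."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["write_pedigree", "read_pedigree", "write_phenotypes", "read_phenotypes",
           "write_snp_file", "read_snp_file", "export_population",
           "load_config", "save_config"]


def write_pedigree(path, pedigree: pd.DataFrame) -> None:
    """CSV with header ``id,sire,dam,sex,generation``; 0 = unknown parent."""
    pedigree.to_csv(path, index=False,
                    columns=["id", "sire", "dam", "sex", "generation"])


def read_pedigree(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("id", "sire", "dam", "generation"):
        df[col] = df[col].astype(np.int64)
    return df


def write_phenotypes(path, ids, phenotypes) -> None:
    pd.DataFrame({"id": np.asarray(ids), "phenotype": np.asarray(phenotypes)}).to_csv(
        path, index=False
    )


def read_phenotypes(path) -> pd.Series:
    df = pd.read_csv(path)
    return pd.Series(df["phenotype"].to_numpy(), index=df["id"].to_numpy(np.int64))


def write_snp_file(path, ids, codes: np.ndarray) -> None:
    """BLUPF90 SNP dialect: animal id, one space run, unbroken 0/1/2 string.

    Code 5 is reserved for missing genotypes; the simulator never emits it.
    """
    codes = np.asarray(codes)
    with open(path, "w") as fh:
        for a, row in zip(np.asarray(ids), codes):
            fh.write(f"{a} {''.join(map(str, row.tolist()))}\n")


def read_snp_file(path):
    """Returns ``(ids, codes)`` from a BLUPF90-style SNP file."""
    ids, rows = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            a, geno = line.split(None, 1)
            ids.append(int(a))
            rows.append(np.frombuffer(geno.strip().encode(), dtype=np.uint8) - ord("0"))
    codes = np.vstack(rows).astype(np.int8) if rows else np.zeros((0, 0), np.int8)
    return np.asarray(ids, dtype=np.int64), codes


def export_population(popn, outdir, training_ids=None, validation_ids=None) -> dict:
    """Write pedigree, phenotype and genotype files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"pedigree": outdir / "pedigree.csv", "phenotypes": outdir / "pheno.csv"}
    write_pedigree(paths["pedigree"], popn.pedigree_frame())
    write_phenotypes(paths["phenotypes"], popn.id, popn.phenotype)
    snp_mask = popn.genome.snp_mask
    if training_ids is not None:
        paths["geno_train"] = outdir / "geno_train.snp"
        write_snp_file(paths["geno_train"], training_ids,
                       popn.genotypes(training_ids)[:, snp_mask])
    if validation_ids is not None:
        paths["geno_val"] = outdir / "geno_val.snp"
        write_snp_file(paths["geno_val"], validation_ids,
                       popn.genotypes(validation_ids)[:, snp_mask])
    return paths


def save_config(path, config) -> None:
    """Dataclass (possibly nested) → human-readable YAML key-value file."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (list, tuple)):
            return [clean(x) for x in obj]
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        return obj

    with open(path, "w") as fh:
        yaml.safe_dump(clean(config), fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
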