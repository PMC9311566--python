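"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (GT field, one sample per animal, handled with
pysam) or as a tab-separated dialect (rows = animals, columns = variants
named ``chrom:pos``, codes 0/1/2/NA).  Pedigrees, event logs, trait
records and summary tables are CSV with documented headers; generating
parameters round-trip through YAML; GRMs are written as dense
float64 binary plus a plain-text id index.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .relmat import GenotypeMatrix
from .simdata import Pedigree, TrueParams

PEDIGREE_COLUMNS = ["animal_id", "sire_id", "dam_id", "sex", "birth_season", "cohort"]


# -- genotypes --------------------------------------------------------------

def write_vcf(genotypes: GenotypeMatrix, path: str | Path) -> None:
    """Write calls as an uncompressed VCF with GT-only FORMAT."""
    path = str(path)
    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(genotypes.variants["chrom"].astype(str)))
    max_pos = int(genotypes.variants["pos"].max()) + 1
    for c in chroms:
        header.contigs.add(c, length=max_pos)
    header.formats.add("GT", 1, "String", "Genotype")
    for aid in genotypes.animal_ids:
        header.add_sample(str(aid))
    gt_codes = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for j, var in enumerate(genotypes.variants.itertuples(index=False)):
            rec = vcf.new_record(
                contig=str(var.chrom),
                start=int(var.pos) - 1,
                alleles=("A", "G"),
                id=f"v{j}",
            )
            col = genotypes.calls[:, j]
            for i, aid in enumerate(genotypes.animal_ids):
                call = int(col[i])
                rec.samples[str(aid)]["GT"] = gt_codes.get(call, (None, None))
            vcf.write(rec)


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read GT calls from a (possibly bgzipped) VCF."""
    rows = []
    calls_cols = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            rows.append({"chrom": rec.contig, "pos": rec.pos, "annotation": rec.id or ""})
            col = np.full(len(samples), -1, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT")
                if gt is not None and None not in gt:
                    col[i] = sum(gt)
            calls_cols.append(col)
    calls = np.column_stack(calls_cols) if calls_cols else np.empty((len(samples), 0), np.int8)
    return GenotypeMatrix(
        animal_ids=np.array(samples),
        variants=pd.DataFrame(rows, columns=["chrom", "pos", "annotation"]),
        calls=calls,
    )


def write_genotypes_tsv(genotypes: GenotypeMatrix, path: str | Path) -> None:
    cols = [
        f"{c}:{p}"
        for c, p in zip(genotypes.variants["chrom"], genotypes.variants["pos"])
    ]
    df = pd.DataFrame(
        genotypes.calls.astype(object), index=genotypes.animal_ids, columns=cols
    )
    df = df.where(genotypes.calls >= 0, "NA")
    df.index.name = "animal_id"
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    chrom, pos = zip(*(c.split(":") for c in df.columns))
    calls = df.to_numpy(dtype=float)
    calls = np.where(np.isnan(calls), -1, calls).astype(np.int8)
    return GenotypeMatrix(
        animal_ids=df.index.to_numpy().astype(str),
        variants=pd.DataFrame(
            {"chrom": chrom, "pos": [int(p) for p in pos], "annotation": ""}
        ),
        calls=calls,
    )


# -- pedigree and events ----------------------------------------------------

def write_pedigree_csv(pedigree: Pedigree, path: str | Path) -> None:
    """Pedigree CSV: standard columns plus one ``comp_<breed>`` per breed."""
    df = pedigree.table.copy()
    breeds = sorted({b for c in pedigree.composition.values() for b in c})
    for b in breeds:
        df[f"comp_{b}"] = [
            pedigree.composition[a].get(b, 0.0) for a in df["animal_id"]
        ]
    df.to_csv(path, index=False)


def read_pedigree_csv(path: str | Path) -> Pedigree:
    df = pd.read_csv(path, keep_default_na=False)
    comp_cols = [c for c in df.columns if c.startswith("comp_")]
    composition = {}
    for row in df.itertuples(index=False):
        comp = {
            c[len("comp_"):]: float(getattr(row, c))
            for c in comp_cols
            if float(getattr(row, c)) > 0
        }
        composition[row.animal_id] = comp
    table = df[PEDIGREE_COLUMNS].copy()
    table["birth_season"] = table["birth_season"].astype(int)
    return Pedigree(table=table, composition=composition)


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[""])
    df["pregnant"] = df["pregnant"].astype(bool)
    df["weaned"] = df["weaned"].astype(bool)
    df["calf_sex"] = df["calf_sex"].fillna("")
    return df


# -- parameters -------------------------------------------------------------

def write_params_yaml(params: TrueParams, path: str | Path) -> None:
    data = {}
    for key, val in vars(params).items():
        if isinstance(val, np.ndarray):
            data[key] = val.tolist()
        elif val is None or isinstance(val, (int, float, str, bool)):
            data[key] = val
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_params_yaml(path: str | Path) -> TrueParams:
    data = yaml.safe_load(Path(path).read_text())
    for key in ("K_a", "K_d", "K_pe"):
        if data.get(key) is not None:
            data[key] = np.array(data[key])
    return TrueParams(**data)


# -- matrices ---------------------------------------------------------------

def write_grm(G: np.ndarray, animal_ids, path_prefix: str | Path) -> None:
    """Dense symmetric float64 binary plus a one-id-per-line index file."""
    prefix = Path(path_prefix)
    np.asarray(G, dtype=np.float64).tofile(str(prefix) + ".bin")
    Path(str(prefix) + ".ids").write_text("\n".join(map(str, animal_ids)) + "\n")


def read_grm(path_prefix: str | Path) -> tuple[np.ndarray, np.ndarray]:
    prefix = Path(path_prefix)
    ids = np.array(Path(str(prefix) + ".ids").read_text().split())
    n = len(ids)
    G = np.fromfile(str(prefix) + ".bin", dtype=np.float64).reshape(n, n)
    return G, ids


def write_redundancy_map(redundancy: dict[int, int], path: str | Path) -> None:
    pd.DataFrame(
        {"pruned": list(redundancy.keys()), "representative": list(redundancy.values())}
    ).to_csv(path, index=False)


def read_redundancy_map(path: str | Path) -> dict[int, int]:
    df = pd.read_csv(path)
    return dict(zip(df["pruned"].astype(int), df["representative"].astype(int)))
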