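"""Readers and writers for the plain-text interchange formats.

Genotypes travel as PLINK text (.ped/.map, whitespace delimited, ``0 0``
for a missing call) or as a delimited additive count matrix plus a SNP
annotation table.  Phenotypes are long-format CSV; covariates and the
simulation ground truth are CSV / JSON.  Only text formats are handled;
binary .bed parsing is out of scope.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix, LinkageRegionTable, TruthRecord

__all__ = [
    "write_plink_text",
    "read_plink_text",
    "write_cohort",
    "read_cohort",
    "read_region_table",
]


def write_plink_text(g: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    """Write ``prefix.ped`` / ``prefix.map`` plus ``prefix.snps.csv``.

    The .map file cannot carry allele identities, so the annotation CSV
    records which allele is counted (minor) — required for a lossless
    round trip when a sample's minor allele drifts past 0.5.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")

    minor = g.snps["minor_allele"].to_numpy()
    major = g.snps["major_allele"].to_numpy()
    with open(ped_path, "w") as ped:
        for i, sid in enumerate(g.subject_ids):
            fields = [sid, sid, "0", "0", "0", "-9"]
            row = g.values[i]
            for k in range(g.n_snps):
                c = row[k]
                if not np.isfinite(c):
                    fields.extend(["0", "0"])
                elif c == 0:
                    fields.extend([major[k], major[k]])
                elif c == 1:
                    fields.extend([minor[k], major[k]])
                else:
                    fields.extend([minor[k], minor[k]])
            ped.write(" ".join(fields) + "\n")

    with open(map_path, "w") as mp:
        for r in g.snps.itertuples():
            mp.write(f"{r.chrom} {r.snp_id} 0 {r.bp}\n")

    g.snps.to_csv(prefix.parent / (prefix.name + ".snps.csv"), index=False)
    return ped_path, map_path


def read_plink_text(
    ped_path: str | Path,
    map_path: str | Path,
    annotations: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Read PLINK text genotypes into minor-allele counts.

    When ``annotations`` (with a ``minor_allele`` column aligned by
    ``snp_id``) is not supplied, the minor allele is inferred per SNP as
    the less frequent allele among observed calls, ties broken
    alphabetically.
    """
    snp_map = pd.read_csv(
        map_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "bp"],
        dtype={"snp_id": str},
    )
    m = len(snp_map)
    subject_ids: list[str] = []
    allele_rows: list[np.ndarray] = []
    with open(ped_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f".ped row has {len(parts)} fields, expected {6 + 2 * m}"
                )
            subject_ids.append(parts[1])
            allele_rows.append(np.array(parts[6:], dtype="U8"))
    alleles = np.stack(allele_rows).reshape(len(subject_ids), m, 2)

    if annotations is not None:
        ann = annotations.set_index("snp_id")
        minor = ann.loc[snp_map["snp_id"], "minor_allele"].to_numpy()
    else:
        minor = np.empty(m, dtype="U8")
        for k in range(m):
            obs = alleles[:, k, :].ravel()
            obs = obs[obs != "0"]
            if obs.size == 0:
                minor[k] = "0"
                continue
            uniq, counts = np.unique(obs, return_counts=True)
            minor[k] = uniq[np.lexsort((uniq, counts))][0]

    missing = alleles == "0"
    values = (alleles == minor[None, :, None]).sum(axis=2).astype(float)
    values[missing.any(axis=2)] = np.nan

    if annotations is not None:
        snps = annotations.copy()
    else:
        majors = np.empty(m, dtype="U8")
        for k in range(m):
            obs = alleles[:, k, :].ravel()
            obs = obs[(obs != "0") & (obs != minor[k])]
            majors[k] = obs[0] if obs.size else "0"
        snps = snp_map[["snp_id", "chrom", "bp"]].copy()
        snps["minor_allele"] = minor
        snps["major_allele"] = majors
        snps["region"] = None
    return GenotypeMatrix(values=values, snps=snps, subject_ids=subject_ids)


def write_cohort(
    cohort: tuple[GenotypeMatrix, pd.DataFrame, pd.DataFrame, TruthRecord],
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write a simulated cohort as PLINK text + CSV + truth JSON."""
    genotypes, phenotypes, covariates, truth = cohort
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ped, mp = write_plink_text(genotypes, out / "genotypes")
    pheno_path = out / "phenotypes.csv"
    covar_path = out / "covariates.csv"
    truth_path = out / "truth.json"
    phenotypes.to_csv(pheno_path, index=False)
    covariates.to_csv(covar_path, index=False)
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "causal_snp_ids": list(truth.causal_snp_ids),
                "causal_effects": np.asarray(truth.causal_effects).tolist(),
                "group_slopes": truth.group_slopes.to_dict(orient="list"),
            },
            fh,
            indent=1,
        )
    return {
        "ped": ped,
        "map": mp,
        "snps": out / "genotypes.snps.csv",
        "phenotypes": pheno_path,
        "covariates": covar_path,
        "truth": truth_path,
    }


def read_cohort(out_dir: str | Path):
    """Read back a cohort written by :func:`write_cohort`."""
    out = Path(out_dir)
    annotations = pd.read_csv(out / "genotypes.snps.csv", dtype={"snp_id": str})
    if "region" in annotations.columns:
        annotations["region"] = annotations["region"].where(
            annotations["region"].notna(), None
        )
    genotypes = read_plink_text(
        out / "genotypes.ped", out / "genotypes.map", annotations=annotations
    )
    phenotypes = pd.read_csv(out / "phenotypes.csv", dtype={"subject_id": str})
    covariates = pd.read_csv(out / "covariates.csv", dtype={"subject_id": str})
    with open(out / "truth.json") as fh:
        truth = json.load(fh)
    return genotypes, phenotypes, covariates, truth


def read_region_table(path: str | Path) -> LinkageRegionTable:
    """Region CSV with columns chrom, band, start_mb, end_mb."""
    table = pd.read_csv(path)
    return LinkageRegionTable(table=table)
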