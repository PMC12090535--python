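"""Reading, writing and validation of the pipeline's text formats.

Conventions: tab-separated, header row; genotype and abundance matrices are
written with lines as rows.  VCF is read for genotypes only (the GT field;
phased and unphased calls are treated identically; positions are irrelevant
to kernel construction).  A run manifest records seeds, chain settings and
realised defaults so a run can be reproduced exactly.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._util import warn
from .kernels import GenotypePanel, KernelMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "write_vcf",
    "read_abundances",
    "write_abundances",
    "read_phenotypes",
    "write_phenotypes",
    "read_kernel",
    "write_kernel",
    "write_manifest",
    "read_manifest",
]


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path: str | Path, format: str | None = None, strict: bool = False) -> GenotypePanel:
    """Load a genotype panel from delimited text or VCF.

    Delimited layout: first column = line id, remaining columns = markers,
    codes in {0,1,2} or {-1,0,1}.  Missing codes (empty / NA) are
    mean-imputed to 2 p_k per marker.  For VCF, each biallelic record
    contributes the alternate-allele dosage; multi-allelic records are
    skipped with a warning (an error under ``strict``).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in (".vcf",) or path.name.endswith(".vcf.gz") else "delimited"
    if format == "vcf":
        return _read_vcf(path, strict=strict)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated line id {dup!r} in genotype file")
    codes = df.to_numpy(dtype=float)
    codes = _impute_missing(codes)
    return GenotypePanel(
        line_ids=df.index.to_numpy(dtype=object),
        codes=codes,
        marker_ids=df.columns.to_numpy(dtype=object),
    )


def _impute_missing(codes: np.ndarray) -> np.ndarray:
    miss = ~np.isfinite(codes)
    if miss.any():
        warn("GENOTYPES_IMPUTED", f"mean-imputed {int(miss.sum())} missing genotype call(s)")
        shift = 1.0 if np.nanmin(codes) < 0 else 0.0
        col_mean = np.nanmean(codes + shift, axis=0)  # = 2 p_k per marker
        fill = np.broadcast_to(col_mean, codes.shape)[miss] - shift
        codes = codes.copy()
        codes[miss] = fill
    return codes


def _read_vcf(path: Path, strict: bool = False) -> GenotypePanel:
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(set(samples)) != len(samples):
            dup = next(s for s in samples if samples.count(s) > 1)
            raise ValueError(f"duplicated sample id {dup!r} in VCF")
        rows, ids = [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                msg = f"non-biallelic record {rec.chrom}:{rec.pos} skipped"
                if strict:
                    raise ValueError(msg)
                warn("MULTIALLELIC_SKIPPED", msg)
                continue
            dose = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    dose.append(np.nan)
                else:
                    dose.append(float(sum(1 for a in gt if a == 1)))
            rows.append(dose)
            ids.append(rec.id or f"{rec.chrom}:{rec.pos}")
    if not rows:
        raise ValueError(f"no usable biallelic records in {path}")
    codes = _impute_missing(np.asarray(rows, dtype=float).T)
    return GenotypePanel(
        line_ids=np.asarray(samples, dtype=object),
        codes=codes,
        marker_ids=np.asarray(ids, dtype=object),
    )


def write_genotypes(panel: GenotypePanel, path: str | Path) -> None:
    df = pd.DataFrame(panel.codes, index=panel.line_ids, columns=panel.marker_ids)
    # preserve integer codes where the panel has them
    if np.allclose(panel.codes, np.round(panel.codes)):
        df = df.astype(int)
    df.to_csv(path, sep="\t", index_label="line")


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    """Write the panel as a minimal VCF with synthetic contig/positions."""
    codes = np.round(panel.codes).astype(int)
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##contig=<ID=chrS,length=%d>\n" % (100 * (panel.n_markers + 1)))
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in panel.line_ids) + "\n")
        for k in range(panel.n_markers):
            calls = "\t".join(gt_of[int(c)] for c in codes[:, k])
            fh.write(f"chrS\t{100 * (k + 1)}\t{panel.marker_ids[k]}\tA\tB\t.\tPASS\t.\tGT\t{calls}\n")


# ---------------------------------------------------------------------------
# abundances and phenotypes


def write_abundances(abundances: pd.DataFrame, path: str | Path) -> None:
    """Write the (line, env)-indexed (or line-indexed) abundance matrix."""
    abundances.to_csv(path, sep="\t")


def read_abundances(path: str | Path) -> pd.DataFrame:
    head = pd.read_csv(path, sep="\t", nrows=0)
    index_cols = [c for c in ("line", "env") if c in head.columns]
    if not index_cols:
        raise ValueError("abundance file must carry a 'line' (and optional 'env') column")
    return pd.read_csv(path, sep="\t", index_col=index_cols)


def write_phenotypes(phenotypes: pd.DataFrame, path: str | Path) -> None:
    phenotypes.to_csv(path, sep="\t", index=False)


def read_phenotypes(
    path: str | Path, genotypes: GenotypePanel | None = None
) -> pd.DataFrame:
    """Load the observation table (line, env, trait columns).

    When a genotype panel is given, rows whose line is not genotyped are
    dropped with a coded warning (the reconciliation count is logged).
    """
    df = pd.read_csv(path, sep="\t")
    cols = {c.lower(): c for c in df.columns}
    rename = {}
    for want, aliases in {"line": ("line", "id", "genotype"), "env": ("env", "environment", "site")}.items():
        for a in aliases:
            if a in cols:
                rename[cols[a]] = want
                break
        else:
            raise ValueError(f"phenotype file lacks a {want!r} column")
    df = df.rename(columns=rename)
    if genotypes is not None:
        known = set(genotypes.line_ids)
        keep = df["line"].isin(known)
        if not keep.all():
            warn(
                "PHENOTYPE_LINES_DROPPED",
                f"dropped {int((~keep).sum())} observation(s) whose line is not genotyped",
            )
        df = df.loc[keep].reset_index(drop=True)
        if df.empty:
            raise ValueError("no phenotype line overlaps the genotype panel")
    return df


# ---------------------------------------------------------------------------
# kernels, truth, manifest


def write_kernel(K: KernelMatrix, path: str | Path) -> None:
    pd.DataFrame(K.entries, index=K.axis_ids, columns=K.axis_ids).to_csv(
        path, sep="\t", index_label=f"kind={K.kind}"
    )


def read_kernel(path: str | Path, kind: str = "G") -> KernelMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    kind_col = df.index.name or ""
    if kind_col.startswith("kind="):
        kind = kind_col.split("=", 1)[1]
    return KernelMatrix(df.to_numpy(dtype=float), df.index.to_numpy(dtype=object), kind=kind)


def write_manifest(manifest: Mapping, path: str | Path) -> None:
    """Key-value run manifest (JSON for machine readability)."""
    with open(path, "w") as fh:
        json.dump(_jsonable(manifest), fh, indent=2, sort_keys=True)
        fh.write("\n")


def _jsonable(x):
    if isinstance(x, Mapping):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple, np.ndarray)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
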