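"""File formats: Matrix-Market triplets, read tables, truth sidecars, YAML config."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .datatypes import CountMatrix
from .synthetic import SyntheticTruth
from .umi import READ_TABLE_COLUMNS


def write_mtx_triplet(counts: CountMatrix, outdir: str | Path) -> None:
    """Write matrix.mtx (genes x barcodes), barcodes.tsv and features.tsv.

    barcodes.tsv has two tab-separated columns (barcode, sample label);
    features.tsv one gene id per line.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.coo_matrix(counts.X))
    with open(outdir / "barcodes.tsv", "w") as fh:
        for b, s in zip(counts.barcodes, counts.sample_of):
            fh.write(f"{b}\t{s}\n")
    with open(outdir / "features.tsv", "w") as fh:
        fh.write("\n".join(counts.genes) + "\n")


def read_mtx_triplet(indir: str | Path) -> CountMatrix:
    """Read a Matrix-Market triplet directory into a CountMatrix.

    The matrix is taken as genes x barcodes; a matrix whose dimensions only
    match transposed is transposed with that interpretation.  Dimension
    mismatches raise a format error naming the offending file.
    """
    indir = Path(indir)
    for name in ("matrix.mtx", "barcodes.tsv", "features.tsv"):
        if not (indir / name).exists():
            raise FileNotFoundError(f"missing {name} in {indir}")
    try:
        X = scipy.io.mmread(str(indir / "matrix.mtx"))
    except Exception as exc:
        raise ValueError(f"malformed matrix.mtx in {indir}: {exc}") from exc
    bc_table = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)
    barcodes = bc_table[0].astype(str).tolist()
    samples = (bc_table[1].astype(str).to_numpy() if bc_table.shape[1] > 1
               else np.full(len(barcodes), "sample1", dtype=object))
    genes = [ln.strip() for ln in open(indir / "features.tsv") if ln.strip()]
    X = sp.csr_matrix(X)
    if X.shape == (len(genes), len(barcodes)):
        pass
    elif X.shape == (len(barcodes), len(genes)):
        X = X.T.tocsr()
    else:
        raise ValueError(
            f"matrix.mtx shape {X.shape} matches neither {len(genes)} genes x "
            f"{len(barcodes)} barcodes nor its transpose")
    return CountMatrix(genes=genes, barcodes=barcodes, X=X,
                       sample_of=np.asarray(samples, dtype=object))


def write_read_table(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_TABLE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_read_table(path: str | Path) -> pd.DataFrame:
    reads = pd.read_csv(path, sep="\t", dtype={"barcode": str, "gene": str,
                                               "umi": str, "reads": np.int64})
    missing = [c for c in READ_TABLE_COLUMNS if c not in reads.columns]
    if missing:
        raise ValueError(f"read table {path} missing columns {missing}")
    return reads


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    """Write ground-truth sidecars (cells, soup profile, markers, programs)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({
        "barcode": truth.barcodes,
        "cell_type": truth.cell_type_labels,
        "sample": truth.sample_labels,
        "soup_fraction": truth.soup_fraction_true,
    }).to_csv(outdir / "truth_cells.csv", index=False)
    pd.DataFrame({"gene": truth.genes,
                  "soup_fraction_of_pool": truth.soup_profile_true,
                  }).to_csv(outdir / "truth_soup_profile.csv", index=False)
    pd.DataFrame([(t, g) for t, gs in truth.marker_sets.items() for g in gs],
                 columns=["cell_type", "gene"]
                 ).to_csv(outdir / "truth_markers.csv", index=False)
    pd.DataFrame([(p.sender, p.receiver, ";".join(p.ligands), ";".join(p.receptors))
                  for p in truth.lr_programs],
                 columns=["sender", "receiver", "ligands", "receptors"]
                 ).to_csv(outdir / "truth_lr_programs.csv", index=False)


def read_lr_pairs(path: str | Path) -> pd.DataFrame:
    pairs = pd.read_csv(path)
    if not {"ligand", "receptor"} <= set(pairs.columns):
        raise ValueError(f"{path} must have a 'ligand,receptor' header")
    return pairs[["ligand", "receptor"]].astype(str)


def load_yaml_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a YAML mapping")
    return cfg
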