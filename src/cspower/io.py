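"""Readers and writers for the plain-text formats the tool exchanges.

Counts travel as TSV/CSV (genes in rows, header = sample IDs) or
MatrixMarket MTX with ``.rownames``/``.colnames`` sidecar files;
proportions and group labels as TSV/CSV.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix

from .errors import InvalidInputError
from .simulator import SimulatedDataset

_SEP = {".tsv": "\t", ".csv": ","}


def _sep_for(path: Path) -> str:
    try:
        return _SEP[path.suffix]
    except KeyError:
        raise InvalidInputError(
            f"unsupported table extension {path.suffix!r} (use .tsv or .csv)"
        ) from None


def read_counts(path) -> pd.DataFrame:
    """Read a genes x samples count matrix (TSV/CSV, or MTX + sidecars)."""
    path = Path(path)
    if path.suffix == ".mtx":
        mat = mmread(path)
        if hasattr(mat, "todense"):
            mat = mat.todense()
        mat = np.asarray(mat)
        rows = Path(str(path) + ".rownames").read_text().split()
        cols = Path(str(path) + ".colnames").read_text().split()
        return pd.DataFrame(mat, index=rows, columns=cols)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def write_counts(counts: pd.DataFrame, path) -> None:
    path = Path(path)
    if path.suffix == ".mtx":
        mmwrite(path, csr_matrix(counts.to_numpy()))
        Path(str(path) + ".rownames").write_text("\n".join(map(str, counts.index)) + "\n")
        Path(str(path) + ".colnames").write_text("\n".join(map(str, counts.columns)) + "\n")
    else:
        counts.to_csv(path, sep=_sep_for(path))


def read_proportions(path) -> pd.DataFrame:
    """Read a samples x cell-types proportion matrix (TSV/CSV)."""
    path = Path(path)
    return pd.read_csv(path, sep=_sep_for(path), index_col=0)


def read_groups(path) -> pd.Series:
    """Read a sample -> group label table (TSV/CSV, two columns)."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0)
    return df.iloc[:, 0]


def write_dataset(dataset: SimulatedDataset, outdir, *, scenario=None,
                  mtx: bool = False) -> dict:
    """Write a simulated dataset as plain-text files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = list(dataset.gene_ids) or [f"gene{i + 1}" for i in range(dataset.n_genes)]
    cts = list(dataset.celltype_ids) or [f"ct{j + 1}" for j in range(dataset.n_celltypes)]
    samples = [f"s{i + 1}" for i in range(dataset.n_samples)]

    counts = pd.DataFrame(dataset.counts, index=genes, columns=samples)
    counts_path = outdir / ("counts.mtx" if mtx else "counts.tsv")
    write_counts(counts, counts_path)

    prop_path = outdir / "proportions.tsv"
    pd.DataFrame(dataset.proportions, index=samples,
                 columns=cts).to_csv(prop_path, sep="\t")
    groups_path = outdir / "groups.tsv"
    pd.DataFrame({"group": np.where(dataset.group == 0, "control", "case")},
                 index=samples).to_csv(groups_path, sep="\t")
    truth_path = outdir / "truth.tsv"
    target = [cts[t] if t >= 0 else "none" for t in dataset.truth.target_celltype]
    pd.DataFrame({
        "gene_id": genes,
        "is_de": dataset.truth.is_de.astype(int),
        "target_celltype": target,
        "lfc": dataset.truth.lfc,
    }).to_csv(truth_path, sep="\t", index=False)
    meta_path = outdir / "metadata.yaml"
    meta = {"n_genes": dataset.n_genes, "n_samples": dataset.n_samples,
            "n_celltypes": dataset.n_celltypes}
    if scenario is not None:
        meta["scenario"] = {k: (v.item() if hasattr(v, "item") else v)
                            for k, v in vars(scenario).items()}
    meta_path.write_text(yaml.safe_dump(meta, sort_keys=False))
    return {"counts": counts_path, "proportions": prop_path,
            "groups": groups_path, "truth": truth_path, "metadata": meta_path}
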