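"""UMI deduplication and sparse feature-by-pixel count matrices.

Reads sharing an identical (pixel, feature, layer, UMI) tuple are PCR
copies of one molecule and collapse to a single count; distinct UMIs count
separately.  UMI collapse is exact-sequence — deterministic and
order-invariant.  Composite multi-mapping names ("a+b") count in their own
rows and are retained in output.

Matrices carry two layers (exon, intron) over a shared pixel axis that
includes every whitelist-defined pixel, so matrices from different runs of
the same grid are column-alignable.  Exchange format is Matrix Market
coordinate files with feature/pixel TSV sidecars, plus one long-form TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .assignment import ReadAssignment

__all__ = ["CountMatrix", "dedup_and_count", "write_matrix", "read_matrix"]

LAYERS = ("exon", "intron")


class CountMatrix:
    """Sparse UMI counts per feature and pixel, in exon and intron layers.

    Rows are feature names (shared across layers), columns are pixel keys
    ``"{x}x{y}"``.  ``feature_meta`` maps feature name to rna_class and
    record kind where known; composite rows have class ``multi``.
    """

    def __init__(
        self,
        feature_names: list[str],
        pixel_keys: list[str],
        layers: dict[str, sp.csr_matrix],
        feature_meta: Optional[pd.DataFrame] = None,
    ):
        if len(set(pixel_keys)) != len(pixel_keys):
            raise ValueError("pixel keys must be unique")
        if len(set(feature_names)) != len(feature_names):
            raise ValueError("feature names must be unique")
        self.feature_names = list(feature_names)
        self.pixel_keys = list(pixel_keys)
        self.layers = layers
        if feature_meta is None:
            feature_meta = pd.DataFrame(
                {"name": self.feature_names, "rna_class": "other"}
            ).set_index("name")
        self.feature_meta = feature_meta

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.feature_names), len(self.pixel_keys)

    def total(self, layer: Optional[str] = None) -> int:
        if layer is not None:
            return int(self.layers[layer].sum())
        return int(sum(m.sum() for m in self.layers.values()))

    def to_frame(self) -> pd.DataFrame:
        """Long-form (feature, pixel, layer, count) with count > 0."""
        rows = []
        for layer, mat in self.layers.items():
            coo = mat.tocoo()
            for i, j, v in zip(coo.row, coo.col, coo.data):
                rows.append(
                    (self.feature_names[i], self.pixel_keys[j], layer, int(v))
                )
        df = pd.DataFrame(rows, columns=["feature", "pixel", "layer", "count"])
        return df.sort_values(["layer", "feature", "pixel"]).reset_index(drop=True)

    def equals(self, other: "CountMatrix") -> bool:
        """Cell-for-cell equality, tolerant of row/column ordering."""
        a, b = self.to_frame(), other.to_frame()
        key = ["layer", "feature", "pixel"]
        a = a.sort_values(key).reset_index(drop=True)
        b = b.sort_values(key).reset_index(drop=True)
        return a.equals(b)

    def drop_features(self, names: Iterable[str]) -> "CountMatrix":
        """A new matrix with the given feature rows removed."""
        drop = set(names)
        keep = [i for i, n in enumerate(self.feature_names) if n not in drop]
        return CountMatrix(
            [self.feature_names[i] for i in keep],
            self.pixel_keys,
            {layer: m[keep, :].tocsr() for layer, m in self.layers.items()},
            self.feature_meta.loc[
                [self.feature_names[i] for i in keep]
            ],
        )


def dedup_and_count(
    assignments: Iterable[ReadAssignment],
    pixel_keys: list[str],
    feature_meta: Optional[pd.DataFrame] = None,
) -> CountMatrix:
    """Collapse PCR duplicates and build the count matrix.

    Each (pixel, feature, layer, UMI) tuple contributes exactly one count
    regardless of how many reads carry it, so the result is invariant to
    the order of the assignment stream.  ``pixel_keys`` lists every
    whitelist pixel; assignments to pixels outside it are rejected.
    """
    pixel_set = set(pixel_keys)
    molecules: set[tuple[str, str, str, str]] = set()
    for a in assignments:
        if a.status != "assigned":
            continue
        pk = a.pixel.key
        if pk not in pixel_set:
            raise ValueError(f"assignment to unknown pixel {pk}")
        molecules.add((pk, a.feature_name, a.layer, a.umi))

    feature_names = sorted({m[1] for m in molecules})
    frow = {n: i for i, n in enumerate(feature_names)}
    pcol = {p: j for j, p in enumerate(pixel_keys)}
    counts: dict[str, dict[tuple[int, int], int]] = {l: {} for l in LAYERS}
    for pk, feat, layer, _umi in molecules:
        cell = (frow[feat], pcol[pk])
        counts[layer][cell] = counts[layer].get(cell, 0) + 1

    shape = (len(feature_names), len(pixel_keys))
    layers = {}
    for layer in LAYERS:
        cells = counts[layer]
        if cells:
            ij = np.array(list(cells.keys()), dtype=np.int64).T
            data = np.fromiter(cells.values(), dtype=np.int64, count=len(cells))
            layers[layer] = sp.csr_matrix((data, (ij[0], ij[1])), shape=shape)
        else:
            layers[layer] = sp.csr_matrix(shape, dtype=np.int64)

    if feature_meta is not None:
        meta = feature_meta[~feature_meta.index.duplicated()].reindex(feature_names)
        meta["rna_class"] = meta["rna_class"].fillna(
            pd.Series(
                {n: "multi" if "+" in n else "other" for n in feature_names}
            )
        )
    else:
        meta = pd.DataFrame(
            {
                "name": feature_names,
                "rna_class": ["multi" if "+" in n else "other" for n in feature_names],
            }
        ).set_index("name")
    return CountMatrix(feature_names, list(pixel_keys), layers, meta)


def write_matrix(matrix: CountMatrix, outdir, prefix: str = "") -> dict[str, str]:
    """Write one Matrix Market file per layer plus TSV sidecars.

    Written files (per layer): ``<prefix><layer>.mtx`` with integer
    entries, ``<prefix>features.tsv`` (name, rna_class) and
    ``<prefix>pixels.tsv`` shared across layers, and a combined long-form
    ``<prefix>counts_long.tsv``.  Reading the files back reproduces the
    matrix exactly.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for layer, mat in matrix.layers.items():
        p = outdir / f"{prefix}{layer}.mtx"
        scipy.io.mmwrite(str(p), mat.tocoo(), field="integer")
        written[layer] = str(p)
    fpath = outdir / f"{prefix}features.tsv"
    meta = matrix.feature_meta.reindex(matrix.feature_names)
    with open(fpath, "w") as fh:
        for name in matrix.feature_names:
            cls = meta.loc[name, "rna_class"] if "rna_class" in meta else "other"
            fh.write(f"{name}\t{cls}\n")
    ppath = outdir / f"{prefix}pixels.tsv"
    with open(ppath, "w") as fh:
        fh.write("\n".join(matrix.pixel_keys) + ("\n" if matrix.pixel_keys else ""))
    lpath = outdir / f"{prefix}counts_long.tsv"
    matrix.to_frame().to_csv(lpath, sep="\t", index=False)
    written.update(features=str(fpath), pixels=str(ppath), long=str(lpath))
    return written


def read_matrix(outdir, prefix: str = "") -> CountMatrix:
    """Read back matrices written by :func:`write_matrix`."""
    outdir = Path(outdir)
    try:
        ftab = pd.read_csv(
            outdir / f"{prefix}features.tsv", sep="\t", header=None,
            names=["name", "rna_class"], dtype=str, keep_default_na=False,
        )
    except pd.errors.EmptyDataError:
        ftab = pd.DataFrame(columns=["name", "rna_class"])
    ppath = outdir / f"{prefix}pixels.tsv"
    pixels = [l.strip() for l in open(ppath) if l.strip()]
    layers = {}
    for layer in LAYERS:
        m = scipy.io.mmread(str(outdir / f"{prefix}{layer}.mtx"))
        layers[layer] = sp.csr_matrix(m, dtype=np.int64)
        layers[layer].resize(len(ftab), len(pixels))
    return CountMatrix(
        list(ftab["name"]), pixels, layers, ftab.set_index("name")
    )


def write_run_summary(path, counters: dict) -> None:
    with open(path, "w") as fh:
        json.dump(counters, fh, indent=2, sort_keys=True)
        fh.write("\n")
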