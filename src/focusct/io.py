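"""Readers and writers: GMT feature sets, p-value TSV, p-value matrix CSV.

Numeric round-trips are full precision (%.17g).  Every CLI run writes a JSON
manifest (input hashes, parameters, seed, package version) next to its
output so results are re-derivable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .family import FeatureUniverse, FocusFamily
from .replicability import PValueMatrix

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "read_pvalues",
    "write_pvalues",
    "read_matrix",
    "write_matrix",
    "family_from_genesets",
    "write_bounds",
    "write_manifest",
]

log = logging.getLogger("focusct")


@dataclass
class GeneSetCollection:
    """Named feature sets in file order, GMT-style."""

    names: list[str] = field(default_factory=list)
    descriptions: list[str] = field(default_factory=list)
    members: list[list[str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.names)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: name <tab> description <tab> member ids.

    Duplicate members within a line are dropped with a warning; duplicate
    set names or empty member lists are errors.
    """
    coll = GeneSetCollection()
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected name, description and "
                    "at least one member (tab-separated)"
                )
            name, description, *members = parts
            members = [m for m in members if m != ""]
            if not members:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in seen:
                raise ValueError(f"{path}: duplicate set name {name!r}")
            seen.add(name)
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                warnings.warn(
                    f"{path}: line {lineno}: set {name!r} has duplicated "
                    "members; deduplicated",
                    RuntimeWarning,
                    stacklevel=2,
                )
            coll.names.append(name)
            coll.descriptions.append(description)
            coll.members.append(deduped)
    if not coll.names:
        raise ValueError(f"{path}: no feature sets found")
    return coll


def write_gmt(path, coll: GeneSetCollection) -> None:
    with open(path, "w") as fh:
        for name, desc, members in zip(coll.names, coll.descriptions, coll.members):
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_pvalues(path) -> tuple[FeatureUniverse, np.ndarray]:
    """Read a 2-column TSV (feature_id, p); header line optional."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two tab-separated columns")
    start = 0
    try:
        float(df.iloc[0, 1])
    except (TypeError, ValueError):
        start = 1  # header line
    ids = df.iloc[start:, 0].tolist()
    pvals = np.empty(len(ids))
    for offset, raw in enumerate(df.iloc[start:, 1]):
        lineno = start + offset + 1
        try:
            val = float(raw)
        except (TypeError, ValueError):
            raise ValueError(f"{path}: line {lineno}: p-value {raw!r} is not numeric")
        if not (0.0 <= val <= 1.0):
            raise ValueError(
                f"{path}: line {lineno}: p-value {val} outside [0, 1]"
            )
        pvals[offset] = val
    return FeatureUniverse(ids), pvals


def write_pvalues(path, universe: FeatureUniverse, pvals) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tp\n")
        for fid, p in zip(universe.feature_ids, np.asarray(pvals, dtype=float)):
            fh.write(f"{fid}\t{p:.17g}\n")


def read_matrix(path) -> PValueMatrix:
    """Read an m×v p-value CSV: header of study names, first column ids."""
    df = pd.read_csv(path, index_col=0, float_precision="round_trip")
    values = df.to_numpy(dtype=float)
    bad = np.argwhere(np.isnan(values) | (values < 0) | (values > 1))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: line {i + 2}: p-value {values[i, j]!r} for study "
            f"{df.columns[j]!r} outside [0, 1]"
        )
    return PValueMatrix(
        values,
        feature_ids=tuple(str(x) for x in df.index),
        study_ids=tuple(str(c) for c in df.columns),
    )


def write_matrix(path, matrix: PValueMatrix) -> None:
    df = pd.DataFrame(
        matrix.values, index=matrix.feature_ids, columns=matrix.study_ids
    )
    df.to_csv(path, float_format="%.17g")


def family_from_genesets(
    universe: FeatureUniverse, coll: GeneSetCollection
) -> FocusFamily:
    """Resolve a gene-set collection against a universe; name missing ids."""
    missing = sorted(
        {m for members in coll.members for m in members if m not in universe}
    )
    if missing:
        shown = ", ".join(missing[:10])
        more = f" (+{len(missing) - 10} more)" if len(missing) > 10 else ""
        raise ValueError(f"feature ids not in universe: {shown}{more}")
    return FocusFamily.from_id_sets(universe, coll.members, names=coll.names)


def write_bounds(path, names, sets, bounds) -> None:
    """Bounds TSV: set_name, size, bound, bound_tdp (= bound / size)."""
    with open(path, "w") as fh:
        fh.write("set_name\tsize\tbound\tbound_tdp\n")
        for name, s, b in zip(names, sets, bounds):
            size = len(s)
            tdp = b / size if size else 0.0
            fh.write(f"{name}\t{size}\t{b}\t{tdp:.17g}\n")


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, inputs=(), **fields) -> None:
    """JSON manifest: input file hashes plus run parameters."""
    from . import __version__

    manifest = {
        "focusct_version": __version__,
        "inputs": {str(p): _sha256(p) for p in inputs},
        **fields,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    log.info("manifest written to %s", path)
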