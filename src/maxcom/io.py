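"""Readers and writers for the plain-text interchange formats.

All identifiers are opaque strings; no symbol-mapping service is ever
called.  Formats:

* similarity: 3-column TSV ``disease_a  disease_b  similarity`` (header
  optional), or a square matrix CSV with disease ids as index/columns;
* PPI: 2-column TSV ``protein_a  protein_b``;
* associations: 2-column TSV ``disease_id  protein_id``;
* complexes: CORUM-style TSV ``complex_id  name  member;member;...`` or
  GMT (``name  description  member  member ...`` per line);
* benchmark truth: 2-column TSV ``disease_id  complex_id``.

Parse errors name the offending line.  Write-then-read of every format
is the identity on the in-memory representation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .network import (
    AssociationList,
    PPIEdgeList,
    ProteinComplex,
    SimilarityTable,
)
from .simulate import BenchmarkTruth

logger = logging.getLogger("maxcom")


def _data_lines(path) -> Iterable[Tuple[int, List[str]]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            yield lineno, line.split("\t")


# -- similarity ----------------------------------------------------------


def read_similarity_tsv(path) -> SimilarityTable:
    """Read 3-column similarity TSV; symmetric duplicates are merged."""
    records = []
    n_rows = 0
    for lineno, fields in _data_lines(path):
        if len(fields) != 3:
            raise ValueError(
                f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        a, b, raw = fields
        try:
            s = float(raw)
        except ValueError:
            if n_rows == 0:
                continue  # optional header row
            raise ValueError(f"{path}:{lineno}: similarity {raw!r} is not a number")
        if not (0.0 <= s <= 1.0):
            raise ValueError(
                f"{path}:{lineno}: similarity {s} outside [0, 1]"
            )
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-pair for disease {a!r}")
        records.append((a, b, s))
        n_rows += 1
    if not records:
        raise ValueError(f"{path}: no similarity records")
    try:
        return SimilarityTable.from_records(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_similarity_tsv(sim: SimilarityTable, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_a\tdisease_b\tsimilarity\n")
        for (a, b), s in sorted(sim.entries.items()):
            fh.write(f"{a}\t{b}\t{s:.17g}\n")


def read_similarity_matrix_csv(path) -> SimilarityTable:
    """Read a square disease-by-disease similarity matrix (CSV, ids on both axes)."""
    df = pd.read_csv(path, index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: matrix index and columns differ")
    values = df.to_numpy(dtype=float)
    if not np.allclose(values, values.T, atol=1e-12):
        raise ValueError(f"{path}: matrix is not symmetric")
    ids = [str(i) for i in df.index]
    records = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            s = float(values[i, j])
            if s != 0.0:
                records.append((ids[i], ids[j], s))
    try:
        return SimilarityTable.from_records(records, diseases=ids)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


# -- PPI and associations -------------------------------------------------


def read_ppi_tsv(path) -> PPIEdgeList:
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        a, b = fields
        if lineno == 1 and {a.lower(), b.lower()} & {"protein_a", "protein_b"}:
            continue
        if a == b:
            raise ValueError(f"{path}:{lineno}: self-interaction for {a!r}")
        records.append((a, b))
    if not records:
        raise ValueError(f"{path}: no PPI records")
    return PPIEdgeList.from_records(records)


def write_ppi_tsv(ppi: PPIEdgeList, path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_a\tprotein_b\n")
        for a, b in sorted(ppi.edges):
            fh.write(f"{a}\t{b}\n")


def read_associations_tsv(path) -> AssociationList:
    records = []
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 tab-separated columns, got {len(fields)}"
            )
        d, p = fields
        if lineno == 1 and {d.lower(), p.lower()} & {"disease_id", "protein_id"}:
            continue
        records.append((d, p))
    if not records:
        raise ValueError(f"{path}: no association records")
    return AssociationList.from_records(records)


def write_associations_tsv(assoc: AssociationList, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tprotein_id\n")
        for d, p in sorted(assoc.pairs):
            fh.write(f"{d}\t{p}\n")


# -- complexes ------------------------------------------------------------


def read_complexes(path, fmt: Optional[str] = None) -> List[ProteinComplex]:
    """Read complexes from CORUM-style TSV or GMT.

    ``fmt`` is ``"corum"`` or ``"gmt"``; by default it is inferred from
    the file extension (``.gmt`` -> GMT, anything else -> CORUM TSV).
    """
    if fmt is None:
        fmt = "gmt" if str(path).endswith(".gmt") else "corum"
    out: List[ProteinComplex] = []
    seen = set()
    for lineno, fields in _data_lines(path):
        if fmt == "corum":
            if len(fields) != 3:
                raise ValueError(
                    f"{path}:{lineno}: expected 3 tab-separated columns, got {len(fields)}"
                )
            cid, name, raw_members = fields
            if lineno == 1 and cid.lower() == "complex_id":
                continue
            members = [m for m in raw_members.split(";") if m]
        elif fmt == "gmt":
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
                )
            cid, name = fields[0], fields[1]
            members = [m for m in fields[2:] if m]
        else:
            raise ValueError(f"unknown complex file format {fmt!r}")
        if not members:
            raise ValueError(f"{path}:{lineno}: complex {cid!r} has no members")
        if cid in seen:
            raise ValueError(f"{path}:{lineno}: duplicate complex id {cid!r}")
        seen.add(cid)
        out.append(ProteinComplex(complex_id=cid, members=frozenset(members), name=name))
    if not out:
        raise ValueError(f"{path}: no complexes")
    return out


def write_complexes_tsv(complexes: Sequence[ProteinComplex], path) -> None:
    with open(path, "w") as fh:
        fh.write("complex_id\tname\tmembers\n")
        for c in sorted(complexes, key=lambda c: c.complex_id):
            fh.write(f"{c.complex_id}\t{c.name}\t{';'.join(sorted(c.members))}\n")


def write_complexes_gmt(complexes: Sequence[ProteinComplex], path) -> None:
    with open(path, "w") as fh:
        for c in sorted(complexes, key=lambda c: c.complex_id):
            fh.write("\t".join([c.complex_id, c.name or "-", *sorted(c.members)]) + "\n")


# -- truth ----------------------------------------------------------------


def read_truth_tsv(path) -> BenchmarkTruth:
    pairs = set()
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        d, c = fields
        if lineno == 1 and d.lower() == "disease_id":
            continue
        pairs.add((d, c))
    return BenchmarkTruth(pairs=frozenset(pairs))


def write_truth_tsv(truth: BenchmarkTruth, path) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tcomplex_id\n")
        for d, c in sorted(truth.pairs):
            fh.write(f"{d}\t{c}\n")


def write_benchmark(outputs, directory) -> Dict[str, str]:
    """Write the five generator outputs into ``directory``; returns the paths."""
    sim, ppi, assoc, complexes, truth = outputs
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "similarity": str(directory / "similarity.tsv"),
        "ppi": str(directory / "ppi.tsv"),
        "associations": str(directory / "associations.tsv"),
        "complexes": str(directory / "complexes.tsv"),
        "truth": str(directory / "truth.tsv"),
    }
    write_similarity_tsv(sim, paths["similarity"])
    write_ppi_tsv(ppi, paths["ppi"])
    write_associations_tsv(assoc, paths["associations"])
    write_complexes_tsv(complexes, paths["complexes"])
    write_truth_tsv(truth, paths["truth"])
    return paths


# -- run configuration ----------------------------------------------------


@dataclass
class RunConfig:
    """End-to-end run settings; defaults match the method's stated settings
    (similarity threshold alpha = 0.1, 99 random controls per run)."""

    similarity_path: str = ""
    ppi_path: str = ""
    association_path: str = ""
    complex_path: str = ""
    alpha: float = 0.1
    denominator_policy: str = "annotated"  # annotated | present
    holdout_policy: str = "all"  # all | query-only
    multi_disease_policy: str = "mean"  # mean | best | per-pair
    n_random_controls: int = 99
    master_seed: int = 0
    roc_grid: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls().__dict__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


def read_inputs(
    config: RunConfig,
) -> Tuple[SimilarityTable, PPIEdgeList, AssociationList, List[ProteinComplex]]:
    """Load and validate the four input layers named by a config."""
    sim = (
        read_similarity_matrix_csv(config.similarity_path)
        if str(config.similarity_path).endswith(".csv")
        else read_similarity_tsv(config.similarity_path)
    )
    ppi = read_ppi_tsv(config.ppi_path)
    assoc = read_associations_tsv(config.association_path)
    complexes = read_complexes(config.complex_path)
    logger.info(
        "inputs: %d diseases, %d similarity pairs, %d proteins, %d PPI edges, "
        "%d associations, %d complexes",
        len(sim.diseases), len(sim), len(ppi.proteins), len(ppi.edges),
        len(assoc), len(complexes),
    )
    return sim, ppi, assoc, complexes
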