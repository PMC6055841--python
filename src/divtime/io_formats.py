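"""Readers and writers: annotated Newick, alignments, calibration tables,
serialized likelihood approximations, YAML configs and run manifests.

Conventions: user-facing tables carry ages in Ma (million years); everything
in memory is in units of 100 Myr.  Newick calibration annotations follow the
quoted-label dialect ``'B(t_L, t_U)'`` (minimum and maximum) and
``'L(t_L)'`` / ``'L(t_L, p, c)'`` (minimum only), attached to internal
nodes, with ages already in 100 Myr units.
"""

from __future__ import annotations

import hashlib
import json
import logging
import re
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
import yaml
from Bio import AlignIO

from divtime.calibrations import CalibrationRecord
from divtime.likelihood import Alignment, BranchLengthApprox
from divtime.time_prior import TimeTree

__all__ = [
    "parse_annotated_newick",
    "write_annotated_newick",
    "read_alignment",
    "load_calibration_table",
    "save_calibration_table",
    "write_inbv",
    "read_inbv",
    "load_config",
    "write_manifest",
]

logger = logging.getLogger("divtime")

_ANNOT = re.compile(
    r"^\s*(?P<kind>[BL])\s*\(\s*(?P<args>[^)]*)\s*\)\s*$"
)


def parse_annotated_newick(text: str) -> tuple[TimeTree, list[CalibrationRecord]]:
    """Parse a Newick string whose internal-node labels carry calibrations.

    Annotated nodes are relabelled ``cal1, cal2, ...`` (preorder) in the
    returned tree's label map, and one :class:`CalibrationRecord` is emitted
    per annotation.  If the tree has branch lengths, node ages are computed
    from them; otherwise placeholder ages proportional to node depth are
    assigned (the topology is what matters downstream).  Malformed
    annotations raise ``ValueError`` with the character offset; an
    annotation on a tip is an error.
    """
    dtree = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    records: list[CalibrationRecord] = []
    counter = 0
    for nd in dtree.preorder_node_iter():
        label = nd.label if not nd.is_leaf() else (
            nd.taxon.label if nd.taxon else None
        )
        if label is None:
            continue
        m = _ANNOT.match(label)
        if m is None:
            if not nd.is_leaf() and re.match(r"^\s*[BL]\s*\(", label):
                offset = max(text.find(label), 0)
                raise ValueError(
                    f"malformed calibration annotation {label!r} at "
                    f"character {offset}"
                )
            continue
        if nd.is_leaf():
            offset = max(text.find(label), 0)
            raise ValueError(
                f"calibration annotation on a tip at character {offset}"
            )
        args = [float(x) for x in m.group("args").split(",") if x.strip()]
        counter += 1
        name = f"cal{counter}"
        if m.group("kind") == "B":
            if len(args) < 2:
                offset = max(text.find(label), 0)
                raise ValueError(
                    f"B(...) needs at least t_L, t_U at character {offset}"
                )
            records.append(CalibrationRecord(name, args[0], args[1]))
        else:
            if len(args) < 1:
                offset = max(text.find(label), 0)
                raise ValueError(
                    f"L(...) needs at least t_L at character {offset}"
                )
            records.append(CalibrationRecord(name, args[0], None))
        nd.label = name

    has_lengths = all(
        e.length is not None for e in dtree.preorder_edge_iter()
        if e.head_node.parent_node is not None
    )
    if not has_lengths:
        _assign_depth_ages(dtree)
    tree = TimeTree.from_dendropy(dtree)
    return tree, records


def _assign_depth_ages(dtree: dendropy.Tree) -> None:
    """Placeholder ultrametric edge lengths proportional to node depth."""
    depth: dict[int, int] = {}
    for nd in dtree.postorder_node_iter():
        depth[id(nd)] = 0 if nd.is_leaf() else 1 + max(
            depth[id(c)] for c in nd.child_nodes()
        )
    for nd in dtree.preorder_node_iter():
        if nd.parent_node is not None:
            nd.edge.length = float(
                depth[id(nd.parent_node)] - depth[id(nd)]
            )


def write_annotated_newick(
    tree: TimeTree, records: list[CalibrationRecord]
) -> str:
    """Serialize a tree with quoted-label calibration annotations.

    The inverse of :func:`parse_annotated_newick` up to label renaming:
    parse(write(tree, records)) recovers the same topology and records.
    """
    dtree = tree.to_dendropy()
    by_label = {rec.node_label: rec for rec in records}
    for nd in dtree.preorder_node_iter():
        if nd.is_leaf() or not nd.label:
            continue
        rec = by_label.get(nd.label)
        if rec is None:
            continue
        if rec.t_max is not None:
            nd.label = f"B({rec.t_min:g}, {rec.t_max:g})"
        else:
            nd.label = f"L({rec.t_min:g})"
    out = dtree.as_string(schema="newick", suppress_rooting=True)
    return out.strip()


def read_alignment(path: str | Path, format: str = "fasta") -> Alignment:
    """Read a FASTA or PHYLIP alignment into the internal container.

    ``format`` is ``fasta`` or ``phylip`` (interleaved and sequential
    dialects are both accepted).  Sequences are uppercased; gaps and
    ambiguity codes are retained as missing states.  Ragged input raises.
    """
    path = Path(path)
    if format == "phylip":
        try:
            msa = AlignIO.read(str(path), "phylip-relaxed")
        except ValueError:
            msa = AlignIO.read(str(path), "phylip-sequential")
    elif format == "fasta":
        msa = AlignIO.read(str(path), "fasta")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")
    seqs = {rec.id: str(rec.seq).upper() for rec in msa}
    if len(seqs) != len(msa):
        raise ValueError(f"duplicate taxa in {path}")
    return Alignment.from_sequences(seqs)


def write_alignment(alignment: Alignment, path: str | Path,
                    format: str = "fasta") -> None:
    path = Path(path)
    seqs = alignment.to_sequences()
    if format == "fasta":
        with open(path, "w") as fh:
            for name, seq in seqs.items():
                fh.write(f">{name}\n{seq}\n")
    elif format == "phylip":
        with open(path, "w") as fh:
            fh.write(f" {len(seqs)} {alignment.n_sites}\n")
            for name, seq in seqs.items():
                fh.write(f"{name}  {seq}\n")
    else:
        raise ValueError(f"unsupported alignment format {format!r}")


def load_calibration_table(path: str | Path) -> list[CalibrationRecord]:
    """Load a calibration TSV (columns node_label, t_min_Ma, t_max_Ma).

    Ages are converted from Ma to 100 Myr units; a missing t_max_Ma makes a
    minimum-only record.  A maximum at or below its minimum raises, naming
    the row.  An empty table returns an empty list with a logged warning.
    """
    df = pd.read_csv(path, sep="\t")
    required = {"node_label", "t_min_Ma", "t_max_Ma"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"calibration table must have columns {sorted(required)}"
        )
    if df.empty:
        logger.warning("calibration table %s is empty", path)
        return []
    records = []
    for i, row in df.iterrows():
        t_min = float(row["t_min_Ma"]) / 100.0
        raw_max = row["t_max_Ma"]
        t_max = None if pd.isna(raw_max) else float(raw_max) / 100.0
        try:
            records.append(CalibrationRecord(str(row["node_label"]), t_min, t_max))
        except ValueError as exc:
            raise ValueError(f"row {i} of {path}: {exc}") from exc
    return records


def save_calibration_table(records: list[CalibrationRecord],
                           path: str | Path) -> None:
    rows = [
        {
            "node_label": r.node_label,
            "t_min_Ma": r.t_min * 100.0,
            "t_max_Ma": "" if r.t_max is None else r.t_max * 100.0,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# in.BV-style serialized likelihood approximations
# ---------------------------------------------------------------------------


def write_inbv(approxes: list[BranchLengthApprox], path: str | Path) -> None:
    """Serialize per-partition (b_hat, gradient, Hessian) quadratic summaries.

    Plain-text layout, one block per partition::

        partition <k> <n_branches> <transform> <loglik_at_mle>
        <b_hat ...>
        <gradient ...>
        <n_branches rows of the Hessian>
    """
    with open(path, "w") as fh:
        fh.write(f"{len(approxes)} partitions\n")
        for k, ap in enumerate(approxes):
            n = len(ap.b_hat)
            fh.write(f"partition {k} {n} {ap.transform} "
                     f"{ap.loglik_at_mle:.10g}\n")
            fh.write(" ".join(f"{x:.12g}" for x in ap.b_hat) + "\n")
            fh.write(" ".join(f"{x:.12g}" for x in ap.gradient) + "\n")
            for row in ap.hessian:
                fh.write(" ".join(f"{x:.12g}" for x in row) + "\n")


def read_inbv(path: str | Path) -> list[BranchLengthApprox]:
    """Read the serialized quadratic summaries written by :func:`write_inbv`.

    Truncated files raise rather than returning partial data.
    """
    lines = Path(path).read_text().splitlines()
    if not lines or "partitions" not in lines[0]:
        raise ValueError(f"{path}: not an in.BV-style file")
    n_parts = int(lines[0].split()[0])
    out = []
    pos = 1
    for _ in range(n_parts):
        if pos >= len(lines):
            raise ValueError(f"{path}: truncated (missing partition header)")
        head = lines[pos].split()
        if head[0] != "partition":
            raise ValueError(f"{path}: bad partition header at line {pos + 1}")
        n = int(head[2])
        transform = head[3]
        loglik = float(head[4])
        need = pos + 3 + n
        if need > len(lines):
            raise ValueError(f"{path}: truncated partition block")
        b_hat = np.fromstring(lines[pos + 1], sep=" ")
        grad = np.fromstring(lines[pos + 2], sep=" ")
        hess = np.array([np.fromstring(lines[pos + 3 + i], sep=" ")
                         for i in range(n)])
        if len(b_hat) != n or len(grad) != n or hess.shape != (n, n):
            raise ValueError(f"{path}: truncated or ragged partition block")
        out.append(BranchLengthApprox(b_hat, grad, hess, transform, loglik))
        pos = need
    return out


# ---------------------------------------------------------------------------
# configuration and run manifests
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_manifest(path: str | Path, config: dict, seeds: dict[str, int]) -> None:
    """Write a reproducibility manifest (config hash, seeds, versions)."""
    import divtime

    payload = {
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "config": config,
        "seeds": seeds,
        "versions": {
            "divtime": getattr(divtime, "__version__", "unknown"),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "dendropy": dendropy.__version__,
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
    logger.info("manifest written to %s", path)
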