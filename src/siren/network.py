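"""Network and expression I/O, plus edge-wise scoring of a whole GRN.

An expression matrix is a pandas DataFrame with gene identifiers as the
index and sample identifiers as columns.  A GRN is an undirected,
deduplicated edge list; the score is symmetric, so directed input rows are
symmetrized and direction is never inferred.  ``sign_network`` applies the
scoring pipeline to every edge and thresholds the scores into predicted
signs (+1 activating, -1 inhibitory, unsigned in between).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .discretize import joint_distribution, membership_matrix
from .errors import DegenerateProfileError, DuplicateGeneError, ParseError
from .score import ScoreConfig, score_joint

__all__ = [
    "Edge",
    "Grn",
    "SignedNetwork",
    "read_expression",
    "read_network",
    "sign_network",
    "write_signed_network",
    "read_signed_network",
]

logger = logging.getLogger(__name__)

#: default signing threshold on |score| (the published operating point)
DEFAULT_THRESHOLD = 0.158

_POSITIVE_TOKENS = {"+", "+1", "1", "positive", "activation", "activates"}
_NEGATIVE_TOKENS = {"-", "−", "-1", "negative", "inhibition", "inhibits"}
_UNKNOWN_TOKENS = {"", "0", "?", "unknown", "na", "nan"}

_NA_TOKENS = {"", "na", "nan", "null", "none", "n/a"}


class Edge(NamedTuple):
    gene_a: str
    gene_b: str
    reference_sign: int = 0  # +1, -1, or 0 for unknown


@dataclass(frozen=True)
class Grn:
    """Undirected, deduplicated edge list with optional reference signs."""

    edges: tuple[Edge, ...]

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.gene_a)
            seen.setdefault(e.gene_b)
        return list(seen)

    def __len__(self) -> int:
        return len(self.edges)

    @classmethod
    def from_edges(cls, rows: Iterable[tuple[str, str, int]]) -> "Grn":
        """Normalize, drop self-loops, deduplicate unordered pairs."""
        dedup: dict[tuple[str, str], int] = {}
        n_self = 0
        for a, b, sign in rows:
            if a == b:
                n_self += 1
                continue
            key = (a, b) if a <= b else (b, a)
            if key in dedup:
                if dedup[key] != sign and sign != 0:
                    if dedup[key] == 0:
                        dedup[key] = sign
                    else:
                        logger.warning(
                            "conflicting reference signs for edge %s-%s; "
                            "keeping the first",
                            *key,
                        )
            else:
                dedup[key] = sign
        if n_self:
            logger.warning("dropped %d self-loop(s)", n_self)
        edges = tuple(Edge(a, b, s) for (a, b), s in sorted(dedup.items()))
        return cls(edges=edges)


@dataclass(frozen=True)
class SignedNetwork:
    """Edge table with scores, predicted signs and reference signs.

    ``frame`` has columns gene_a, gene_b, score, predicted_sign,
    reference_sign; signs are +1 / -1 / 0 (0 = unsigned / unknown).
    Degenerate edges (constant profile) have NaN score and sign 0.
    """

    frame: pd.DataFrame
    threshold: float

    def __len__(self) -> int:
        return len(self.frame)


def parse_sign_token(token: str) -> int:
    t = str(token).strip().lower()
    if t in _POSITIVE_TOKENS:
        return 1
    if t in _NEGATIVE_TOKENS:
        return -1
    if t in _UNKNOWN_TOKENS:
        return 0
    raise ParseError(f"unrecognized interaction sign token {token!r}")


def read_expression(
    path: str | Path, missing: str = "error"
) -> pd.DataFrame:
    """Read a genes x samples tab-separated expression matrix.

    First column gene identifiers, header row sample identifiers, numeric
    body.  ``missing='error'`` (default) rejects NA cells; ``'allow'``
    keeps them as NaN for pairwise-complete handling downstream.
    """
    if missing not in ("error", "allow"):
        raise ValueError("missing must be 'error' or 'allow'")
    raw = pd.read_csv(
        path, sep="\t", index_col=0, dtype=str, keep_default_na=False,
        comment="#",
    )
    dupes = raw.index[raw.index.duplicated()].unique().tolist()
    if dupes:
        raise DuplicateGeneError(
            f"duplicated gene identifier(s): {', '.join(map(str, dupes))}"
        )
    values = np.empty(raw.shape, dtype=float)
    for j, col in enumerate(raw.columns):
        parsed = pd.to_numeric(raw[col], errors="coerce")
        bad = parsed.isna()
        if bad.any():
            tokens = raw[col][bad]
            for gene, tok in tokens.items():
                if tok.strip().lower() not in _NA_TOKENS:
                    raise ParseError(
                        f"non-numeric value {tok!r} at gene {gene!r}, "
                        f"sample {col!r}"
                    )
            if missing == "error":
                gene = tokens.index[0]
                raise ParseError(
                    f"missing value at gene {gene!r}, sample {col!r} "
                    "(pass missing='allow' for pairwise-complete handling)"
                )
        values[:, j] = parsed.to_numpy()
    return pd.DataFrame(values, index=raw.index, columns=raw.columns)


def _read_network_tsv(path: Path) -> list[tuple[str, str, int]]:
    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if ln == 1 and parts[0].strip().lower() in {"gene_a", "source", "from"}:
                continue  # header row
            if len(parts) < 2:
                raise ParseError(f"{path}:{ln}: expected at least 2 columns")
            sign = parse_sign_token(parts[2]) if len(parts) >= 3 else 0
            rows.append((parts[0].strip(), parts[1].strip(), sign))
    return rows


def _read_network_sif(path: Path) -> list[tuple[str, str, int]]:
    """Simple interaction format: source, relation, one or more targets."""
    rows: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise ParseError(
                    f"{path}:{ln}: SIF rows need source, relation, target(s)"
                )
            source, relation = parts[0], parts[1]
            try:
                sign = parse_sign_token(relation)
            except ParseError:
                sign = 0  # relation type that carries no sign information
            for target in parts[2:]:
                rows.append((source, target, sign))
    return rows


def read_network(path: str | Path, format: str | None = None) -> Grn:
    """Read a GRN edge list from TSV or SIF.

    TSV columns: gene_a, gene_b, optional sign (+/-/+1/-1/activation/
    inhibition/unknown).  Format is inferred from the .sif extension when
    not given.  Edges are symmetrized and deduplicated; self-loops are
    dropped with a logged count.
    """
    path = Path(path)
    if format is None:
        format = "sif" if path.suffix.lower() == ".sif" else "tsv"
    if format == "tsv":
        rows = _read_network_tsv(path)
    elif format == "sif":
        rows = _read_network_sif(path)
    else:
        raise ValueError(f"unknown network format {format!r}")
    return Grn.from_edges(rows)


def _threshold_sign(score: float, threshold: float) -> int:
    if math.isnan(score):
        return 0
    if score >= threshold:
        return 1
    if score <= -threshold:
        return -1
    return 0


def sign_network(
    grn: Grn,
    expr: pd.DataFrame,
    config: ScoreConfig | None = None,
    threshold: float = DEFAULT_THRESHOLD,
) -> SignedNetwork:
    """Score every edge of a GRN and threshold into predicted signs.

    Edges whose genes lack expression data are skipped (with a logged
    count); edges with a constant profile are kept but left unsigned.
    Membership matrices are computed once per gene and reused across
    edges.  Deterministic given inputs and configuration.
    """
    config = config or ScoreConfig()
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    available = set(expr.index)
    needed = [g for g in grn.genes if g in available]
    n_skipped = 0

    has_nan = bool(expr.loc[needed].isna().any().any()) if needed else False
    cache: dict[str, object] = {}

    def gene_membership(gene: str):
        if gene not in cache:
            try:
                cache[gene] = membership_matrix(
                    expr.loc[gene].to_numpy(dtype=float),
                    config.discretization,
                    gene,
                )
            except DegenerateProfileError:
                cache[gene] = None
        return cache[gene]

    records = []
    for edge in grn.edges:
        if edge.gene_a not in available or edge.gene_b not in available:
            n_skipped += 1
            continue
        score = _edge_score(edge, expr, config, gene_membership, has_nan)
        records.append(
            (
                edge.gene_a,
                edge.gene_b,
                score,
                _threshold_sign(score, threshold),
                edge.reference_sign,
            )
        )
    if n_skipped:
        logger.warning(
            "skipped %d edge(s) with genes absent from the expression matrix",
            n_skipped,
        )
    frame = pd.DataFrame(
        records,
        columns=["gene_a", "gene_b", "score", "predicted_sign", "reference_sign"],
    )
    frame = frame.sort_values(["gene_a", "gene_b"], kind="stable").reset_index(
        drop=True
    )
    return SignedNetwork(frame=frame, threshold=threshold)


def _edge_score(edge, expr, config, gene_membership, has_nan) -> float:
    if has_nan:
        # pairwise-complete: drop samples missing in either profile
        x = expr.loc[edge.gene_a].to_numpy(dtype=float)
        y = expr.loc[edge.gene_b].to_numpy(dtype=float)
        keep = ~(np.isnan(x) | np.isnan(y))
        if keep.sum() < 3:
            logger.warning(
                "edge %s-%s has <3 complete samples; left unsigned",
                edge.gene_a,
                edge.gene_b,
            )
            return float("nan")
        try:
            mx = membership_matrix(x[keep], config.discretization, edge.gene_a)
            my = membership_matrix(y[keep], config.discretization, edge.gene_b)
        except DegenerateProfileError:
            logger.warning(
                "edge %s-%s involves a constant profile; left unsigned",
                edge.gene_a,
                edge.gene_b,
            )
            return float("nan")
        return score_joint(joint_distribution(mx, my), config)

    mx = gene_membership(edge.gene_a)
    my = gene_membership(edge.gene_b)
    if mx is None or my is None:
        logger.warning(
            "edge %s-%s involves a constant profile; left unsigned",
            edge.gene_a,
            edge.gene_b,
        )
        return float("nan")
    return score_joint(joint_distribution(mx, my), config)


_SIGN_OUT = {1: "+1", -1: "-1", 0: "unsigned"}
_REF_OUT = {1: "+1", -1: "-1", 0: "unknown"}
_SIGN_IN = {"+1": 1, "-1": -1, "unsigned": 0}
_REF_IN = {"+1": 1, "-1": -1, "unknown": 0}


def write_signed_network(sn: SignedNetwork, path: str | Path) -> None:
    """Write a signed network as TSV, scores at 6 decimal places.

    Columns: gene_a, gene_b, score, predicted_sign, reference_sign; rows
    sorted by (gene_a, gene_b).  NaN scores are written as NA.
    """
    frame = sn.frame.sort_values(["gene_a", "gene_b"], kind="stable")
    with open(path, "w") as fh:
        fh.write("gene_a\tgene_b\tscore\tpredicted_sign\treference_sign\n")
        for row in frame.itertuples(index=False):
            score = "NA" if math.isnan(row.score) else f"{row.score:.6f}"
            fh.write(
                f"{row.gene_a}\t{row.gene_b}\t{score}\t"
                f"{_SIGN_OUT[row.predicted_sign]}\t{_REF_OUT[row.reference_sign]}\n"
            )


def read_signed_network(
    path: str | Path, threshold: float = DEFAULT_THRESHOLD
) -> SignedNetwork:
    """Read back a signed-network TSV written by :func:`write_signed_network`."""
    frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    expected = ["gene_a", "gene_b", "score", "predicted_sign", "reference_sign"]
    if list(frame.columns) != expected:
        raise ParseError(f"expected columns {expected}, got {list(frame.columns)}")
    frame["score"] = [
        float("nan") if s == "NA" else float(s) for s in frame["score"]
    ]
    try:
        frame["predicted_sign"] = [_SIGN_IN[s] for s in frame["predicted_sign"]]
        frame["reference_sign"] = [_REF_IN[s] for s in frame["reference_sign"]]
    except KeyError as exc:
        raise ParseError(f"unrecognized sign token {exc.args[0]!r}") from exc
    return SignedNetwork(frame=frame, threshold=threshold)
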