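"""Tumor-microenvironment gene-signature registry and signature scoring.

A *TME signature* is a named gene set whose average normalized expression
across its member genes summarizes one component or functional property of
the tumor microenvironment (e.g. ``T_cell_traffic``, ``Macrophages``).
Signatures are organized into four functional groups — antitumor immune,
protumor immune, angiogenesis/stroma, and malignant properties — which also
define the task grouping of the multi-task MIL model.

The bundled registry of 30 signatures ships with small illustrative
marker-gene sets; users with access to published gene-set definitions can
substitute their own GMT file anywhere a registry is accepted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical functional-group labels, in display order.
FUNCTIONAL_GROUPS = (
    "antitumor_immune",
    "protumor_immune",
    "angiogenesis_stroma",
    "malignant_properties",
)


class SignatureError(ValueError):
    """Raised for malformed signature registries or unscorable signatures."""


@dataclass(frozen=True)
class SignatureSet:
    """An ordered registry of named gene sets with functional-group labels.

    Parameters
    ----------
    names
        Signature identifiers in canonical order (this order defines the
        column order of every :class:`SignatureProfile`).
    gene_sets
        Mapping from signature name to its member gene symbols.
    groups
        Mapping from signature name to one of :data:`FUNCTIONAL_GROUPS`.
    """

    names: tuple[str, ...]
    gene_sets: Mapping[str, tuple[str, ...]]
    groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise SignatureError("duplicate signature names in registry")
        for name in self.names:
            genes = self.gene_sets.get(name, ())
            if len(genes) == 0:
                raise SignatureError(f"signature {name!r} has an empty gene set")
            if name not in self.groups:
                raise SignatureError(f"signature {name!r} has no group label")

    def __len__(self) -> int:
        return len(self.names)

    def members(self, group: str) -> tuple[str, ...]:
        """Signatures belonging to ``group``, in canonical order."""
        return tuple(n for n in self.names if self.groups[n] == group)

    def group_partition(self) -> dict[str, tuple[str, ...]]:
        """Partition of the registry by functional group (non-empty groups)."""
        out = {}
        for g in dict.fromkeys(self.groups[n] for n in self.names):
            out[g] = self.members(g)
        return out


@dataclass
class SignatureProfile:
    """Per-sample signature scores: one row per sample, one column per signature."""

    scores: pd.DataFrame  # samples x signatures
    provenance: str = "measured"  # "measured" | "predicted"
    coverage: dict[str, float] = field(default_factory=dict)

    @property
    def samples(self) -> list[str]:
        return list(self.scores.index)

    @property
    def signature_names(self) -> list[str]:
        return list(self.scores.columns)

    def values(self) -> np.ndarray:
        return self.scores.to_numpy(dtype=float)


def read_gmt(path: str | Path, groups: Mapping[str, str] | None = None) -> SignatureSet:
    """Parse a GMT file into a :class:`SignatureSet`.

    The GMT description field may carry the group label as ``group=<label>``;
    otherwise supply ``groups`` explicitly. File order is preserved as the
    canonical signature order. Repeated gene symbols within a line are
    deduplicated (first occurrence wins) with a logged warning.
    """
    names: list[str] = []
    gene_sets: dict[str, tuple[str, ...]] = {}
    parsed_groups: dict[str, str] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        if not raw.strip():
            continue
        fields = raw.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise SignatureError(f"{path}:{lineno}: GMT line needs name, description, >=1 gene")
        name, desc, genes = fields[0], fields[1], [g for g in fields[2:] if g]
        if name in gene_sets:
            raise SignatureError(f"{path}:{lineno}: duplicate signature name {name!r}")
        if not genes:
            raise SignatureError(f"{path}:{lineno}: signature {name!r} has no genes")
        deduped = tuple(dict.fromkeys(genes))
        if len(deduped) < len(genes):
            logger.warning("signature %s: %d duplicate gene symbol(s) dropped", name, len(genes) - len(deduped))
        names.append(name)
        gene_sets[name] = deduped
        if desc.startswith("group="):
            parsed_groups[name] = desc[len("group="):]
    if groups is not None:
        parsed_groups.update(groups)
    missing = [n for n in names if n not in parsed_groups]
    if missing:
        raise SignatureError(f"no group label for signatures: {missing}")
    return SignatureSet(tuple(names), gene_sets, parsed_groups)


def write_gmt(sigs: SignatureSet, path: str | Path) -> None:
    """Write a registry back to GMT, embedding group labels in the description."""
    lines = []
    for name in sigs.names:
        lines.append("\t".join([name, f"group={sigs.groups[name]}", *sigs.gene_sets[name]]))
    Path(path).write_text("\n".join(lines) + "\n")


def default_registry() -> SignatureSet:
    """The bundled 30-signature registry in 4 functional groups."""
    ref = resources.files("histotme.data").joinpath("tme_signatures_default.gmt")
    with resources.as_file(ref) as p:
        return read_gmt(p)


def read_expression(path: str | Path) -> pd.DataFrame:
    """Read a genes x samples TPM matrix from TSV/CSV (first column = gene symbol)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    validate_expression(df)
    return df


def validate_expression(expr: pd.DataFrame) -> None:
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise SignatureError(f"duplicate gene symbols: {dups[:5]}")
    vals = expr.to_numpy(dtype=float)
    if not np.isfinite(vals).all():
        raise SignatureError("expression matrix contains non-finite values")
    if (vals < 0).any():
        raise SignatureError("TPM values must be non-negative")


def normalize_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """log2(TPM+1) then per-gene z-score across samples.

    Genes with zero variance across the cohort map to all-zero rows.
    Requires at least two samples (the z-score is otherwise undefined).
    Sample standard deviation (ddof=1) is used.
    """
    validate_expression(expr)
    if expr.shape[1] < 2:
        raise SignatureError("normalization requires >= 2 samples")
    logged = np.log2(expr.to_numpy(dtype=float) + 1.0)
    mu = logged.mean(axis=1, keepdims=True)
    sd = logged.std(axis=1, ddof=1, keepdims=True)
    z = np.divide(logged - mu, sd, out=np.zeros_like(logged), where=sd > 0)
    return pd.DataFrame(z, index=expr.index, columns=expr.columns)


def score_signatures(
    expr_norm: pd.DataFrame,
    sigs: SignatureSet,
    min_coverage: float = 0.5,
) -> SignatureProfile:
    """Average normalized expression of each signature's genes, per sample.

    Missing genes are dropped with a warning; a signature matching fewer than
    ``min_coverage`` of its genes (or none at all) is an error, because the
    mean over a sliver of a gene set no longer measures what the signature
    names.
    """
    cols: dict[str, np.ndarray] = {}
    coverage: dict[str, float] = {}
    index_set = pd.Index(expr_norm.index)
    for name in sigs.names:
        genes = list(sigs.gene_sets[name])
        present = [g for g in genes if g in index_set]
        frac = len(present) / len(genes)
        coverage[name] = frac
        if not present:
            raise SignatureError(f"signature {name!r}: no member genes found in matrix")
        if frac < min_coverage:
            raise SignatureError(
                f"signature {name!r}: only {len(present)}/{len(genes)} genes matched "
                f"(coverage {frac:.2f} < {min_coverage})"
            )
        if frac < 1.0:
            logger.warning(
                "signature %s: %d/%d genes missing from matrix",
                name, len(genes) - len(present), len(genes),
            )
        cols[name] = expr_norm.loc[present].to_numpy(dtype=float).mean(axis=0)
    scores = pd.DataFrame(cols, index=expr_norm.columns)[list(sigs.names)]
    return SignatureProfile(scores=scores, provenance="measured", coverage=coverage)
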