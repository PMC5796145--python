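"""Gene signatures and their probe-level realization on a platform.

A signature is a named set of gene symbols; mapping resolves it to the
probes of an expression matrix by case-insensitive symbol match.  The
50-gene breast cancer intrinsic list (PAM50) ships with the package as
symbols only — it is used here purely as a tumor-genotype-reflecting
gene set, not for subtype classification.  Stromal / microenvironment
signatures are loaded from user-supplied files (plain symbol lists or
GMT).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

from .matrix import ExpressionMatrix

#: Signatures resolvable by name instead of path.
PACKAGED = {"pam50": "pam50.txt"}


@dataclass(frozen=True)
class GeneSignature:
    """A named set of gene symbols (stored case-folded)."""

    name: str
    symbols: frozenset[str]
    source: str = ""

    def __post_init__(self) -> None:
        if not self.symbols:
            raise ValueError(f"signature {self.name!r} has no symbols")

    def __len__(self) -> int:
        return len(self.symbols)


@dataclass(frozen=True)
class SignatureMapping:
    """A signature realized as probes on one platform."""

    signature_name: str
    matched_symbols: frozenset[str]
    probe_ids: tuple[str, ...]
    n_symbols_input: int
    n_symbols_matched: int
    n_probes: int

    def __post_init__(self) -> None:
        assert self.n_symbols_matched <= self.n_symbols_input
        assert self.n_probes == len(self.probe_ids)


def _normalize(symbol: str) -> str:
    return symbol.strip().casefold()


def load_signature(path_or_name) -> GeneSignature:
    """Load a signature from a file, or a packaged list by name.

    Files are either plain text (one symbol per line, ``#`` comments
    allowed) or GMT (``name<TAB>description<TAB>symbol...``; first set
    taken).  Symbols are case-folded and deduplicated, with a warning
    when duplicates were present.
    """
    key = str(path_or_name).casefold()
    if key in PACKAGED:
        ref = resources.files("pairdissect.data") / PACKAGED[key]
        text = ref.read_text()
        return _parse_plain(text, name=key.upper(), source="packaged")
    path = Path(path_or_name)
    text = path.read_text()
    first = next((l for l in text.splitlines() if l.strip()), "")
    if "\t" in first:
        return _parse_gmt(text, source=str(path))
    return _parse_plain(text, name=path.stem, source=str(path))


def _dedup(raw: list[str], name: str) -> frozenset[str]:
    symbols = [_normalize(s) for s in raw if _normalize(s)]
    if not symbols:
        raise ValueError(f"signature {name!r} is empty")
    unique = frozenset(symbols)
    if len(unique) < len(symbols):
        warnings.warn(
            f"signature {name!r}: {len(symbols) - len(unique)} duplicate "
            "symbols removed"
        )
    return unique


def _parse_plain(text: str, name: str, source: str) -> GeneSignature:
    raw = [l for l in text.splitlines() if l.strip() and not l.startswith("#")]
    return GeneSignature(name=name, symbols=_dedup(raw, name), source=source)


def _parse_gmt(text: str, source: str) -> GeneSignature:
    line = next(l for l in text.splitlines() if l.strip())
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 3:
        raise ValueError("GMT line needs name, description and >= 1 symbol")
    name, _desc, *raw = fields
    return GeneSignature(name=name, symbols=_dedup(raw, name), source=source)


def map_symbols_to_probes(
    signature: GeneSignature, matrix: ExpressionMatrix
) -> SignatureMapping:
    """Resolve a signature to the matrix probes carrying its symbols.

    Matching is case-insensitive with whitespace stripped; probe order
    follows the matrix.  Counts report how many input symbols were found
    on the platform and by how many probes.
    """
    if matrix.symbols is None:
        raise ValueError("matrix has no gene-symbol annotations")
    folded = matrix.symbols.fillna("").map(_normalize)
    hit = folded.isin(signature.symbols)
    probes = tuple(matrix.probe_ids[hit])
    matched = frozenset(folded[hit])
    return SignatureMapping(
        signature_name=signature.name,
        matched_symbols=matched,
        probe_ids=probes,
        n_symbols_input=len(signature),
        n_symbols_matched=len(matched),
        n_probes=len(probes),
    )


def write_mapping_report(mapping: SignatureMapping, path) -> None:
    """TSV report: one row per probe, plus the match counts as a header."""
    with open(path, "w") as fh:
        fh.write(f"# signature={mapping.signature_name}\n")
        fh.write(
            f"# n_symbols_input={mapping.n_symbols_input}\t"
            f"n_symbols_matched={mapping.n_symbols_matched}\t"
            f"n_probes={mapping.n_probes}\n"
        )
        pd.Series(mapping.probe_ids, name="probe_id").to_csv(
            fh, sep="\t", index=False
        )
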