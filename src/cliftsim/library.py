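"""Combinatorial peptide-library design.

Libraries are built from residue tokens: the 20 canonical amino acids plus an
open-ended registry of extended building blocks (biotin, propargyl-glycine
"Pra", arbitrary modified monomers) — the method's repertoire is limited only
by which donor slides exist, so tokens are free-form text validated against a
user-extendable registry.

Sequences are stored in synthesis order: solid-phase synthesis elongates
C→N, so residue 1 is the surface-proximal, first-coupled monomer (= layer 1
of the build).  The conventional display is N→C with hyphen-separated
three-letter tokens; figure captions for surface probes list tokens
surface-first instead, available as :attr:`PeptideSequence.surface_str`.

A permutation scan between two equal-length parent epitopes couples, at every
position where the parents differ, either parent's residue — 2^d variants for
d differing positions.  The HA (Tyr-Pro-Tyr-Asp-Val-Pro-Asp-Tyr-Ala) and
Flag (Tyr-Asp-Tyr-Lys-Asp-Asp-Asp-Asp-Lys) epitopes differ at six positions,
giving the 64-member scan (62 non-parental variants).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ResidueToken",
    "PeptideSequence",
    "PermutationScan",
    "SequenceError",
    "EXTENDED_TOKENS",
    "register_token",
    "parse_sequence",
    "diff_positions",
    "permutation_variants",
    "alternating_probe",
    "layer_blocks",
    "read_library_tsv",
    "write_library_tsv",
    "write_fasta",
    "HA",
    "FLAG",
]


class SequenceError(ValueError):
    """Malformed residue token or incompatible sequences."""


THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}

#: extended (non-canonical) building blocks known out of the box
EXTENDED_TOKENS: set[str] = {"biotin", "Pra"}


def register_token(token: str) -> None:
    """Add a non-canonical building block to the registry."""
    if not token:
        raise SequenceError("token must be non-empty")
    EXTENDED_TOKENS.add(token)


@dataclass(frozen=True)
class ResidueToken:
    """One building block: a canonical amino acid (three-letter form) or a
    registered extended token.  ``activated`` marks an OPfp ester (couples
    directly) as opposed to a free acid needing in-situ activation."""

    token: str
    activated: bool = True

    def __post_init__(self) -> None:
        if not self.token:
            raise SequenceError("token must be non-empty")
        canon = self.token.capitalize() if len(self.token) == 3 else self.token
        if canon in THREE_TO_ONE:
            object.__setattr__(self, "token", canon)
        elif len(self.token) == 1 and self.token.upper() in ONE_TO_THREE:
            object.__setattr__(self, "token", ONE_TO_THREE[self.token.upper()])
        elif self.token not in EXTENDED_TOKENS:
            raise SequenceError(
                f"unknown residue token {self.token!r}; register extended "
                "blocks with register_token()"
            )

    @property
    def is_canonical(self) -> bool:
        return self.token in THREE_TO_ONE

    @property
    def one_letter(self) -> str:
        if not self.is_canonical:
            raise SequenceError(f"{self.token!r} has no one-letter code")
        return THREE_TO_ONE[self.token]

    def __str__(self) -> str:  # pragma: no cover - trivial
        return self.token


@dataclass(frozen=True)
class PeptideSequence:
    """Ordered residue tokens in synthesis order (C-terminus first)."""

    residues: tuple
    id: str = ""

    def __post_init__(self) -> None:
        residues = tuple(
            r if isinstance(r, ResidueToken) else ResidueToken(r)
            for r in self.residues
        )
        if len(residues) < 1:
            raise SequenceError("sequence needs at least one residue")
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def display(self) -> str:
        """Conventional N→C display, hyphen-separated three-letter tokens."""
        return "-".join(r.token for r in reversed(self.residues))

    @property
    def surface_str(self) -> str:
        """Surface-first (synthesis-order) form, as probe captions list it."""
        return "-".join(r.token for r in self.residues)

    def __str__(self) -> str:
        return self.display


def parse_sequence(text: str, id: str = "", *, n_to_c: bool = True) -> PeptideSequence:
    """Parse a hyphen-separated token string (or compact one-letter run).

    ``n_to_c=True`` (the display convention) reverses the tokens into
    synthesis order.  Round-trips exactly with :attr:`PeptideSequence.display`.
    """
    text = text.strip()
    if not text:
        raise SequenceError("empty sequence string")
    if "-" in text:
        tokens = text.split("-")
    elif (
        text.capitalize() in THREE_TO_ONE
        or text in EXTENDED_TOKENS
        or not all(ch.upper() in ONE_TO_THREE for ch in text)
    ):
        tokens = [text]          # a single token wins over a one-letter run
    else:
        tokens = list(text)
    try:
        residues = [ResidueToken(t) for t in tokens]
    except SequenceError as exc:
        for i, t in enumerate(tokens, start=1):
            try:
                ResidueToken(t)
            except SequenceError:
                raise SequenceError(
                    f"{id or text!r}: bad token {t!r} at position {i}"
                ) from exc
        raise
    if n_to_c:
        residues = residues[::-1]
    return PeptideSequence(tuple(residues), id=id)


#: the two printed parent epitopes of the 64-variant scan
HA = parse_sequence("Tyr-Pro-Tyr-Asp-Val-Pro-Asp-Tyr-Ala", id="HA")
FLAG = parse_sequence("Tyr-Asp-Tyr-Lys-Asp-Asp-Asp-Asp-Lys", id="Flag")


# ---------------------------------------------------------------------------
# Permutation scans
# ---------------------------------------------------------------------------

def diff_positions(a: PeptideSequence, b: PeptideSequence) -> list[int]:
    """1-based positions (N→C display order) where the parents differ."""
    if len(a) != len(b):
        raise SequenceError(
            f"parents differ in length ({len(a)} vs {len(b)})"
        )
    ra, rb = a.residues[::-1], b.residues[::-1]  # display order
    return [i + 1 for i, (x, y) in enumerate(zip(ra, rb)) if x.token != y.token]


def permutation_variants(
    a: PeptideSequence, b: PeptideSequence, *, id_prefix: str | None = None
) -> list[PeptideSequence]:
    """All 2^d sequences choosing a's or b's token at each differing position.

    Deterministic binary-counting order: variant v has bit string
    ``format(v, '0db')`` over the differing positions in display order, with
    0 = parent a's token; v=0 is parent a, v=2^d−1 is parent b.  Variant ids
    encode the choice vector, e.g. ``HAxFlag-010011``.
    """
    d_pos = diff_positions(a, b)
    d = len(d_pos)
    prefix = id_prefix if id_prefix is not None else f"{a.id or 'A'}x{b.id or 'B'}"
    ra, rb = a.residues[::-1], b.residues[::-1]  # display order
    variants = []
    for v in range(2**d):
        bits = format(v, f"0{d}b") if d else ""
        residues = list(ra)
        for bit, pos in zip(bits, d_pos):
            if bit == "1":
                residues[pos - 1] = rb[pos - 1]
        seq_id = f"{prefix}-{bits}" if d else prefix
        variants.append(PeptideSequence(tuple(residues[::-1]), id=seq_id))
    return variants


@dataclass(frozen=True)
class PermutationScan:
    """A two-parent permutation scan and its full variant set."""

    parent_a: PeptideSequence
    parent_b: PeptideSequence

    @property
    def diff_positions(self) -> list[int]:
        return diff_positions(self.parent_a, self.parent_b)

    @property
    def variants(self) -> list[PeptideSequence]:
        return permutation_variants(self.parent_a, self.parent_b)

    @property
    def non_parental(self) -> list[PeptideSequence]:
        """Variants excluding the two parents (62 for the HA/Flag scan)."""
        parents = {self.parent_a.display, self.parent_b.display}
        return [v for v in self.variants if v.display not in parents]


# ---------------------------------------------------------------------------
# Probes and layer decomposition
# ---------------------------------------------------------------------------

def alternating_probe(
    motif: Sequence[str | ResidueToken],
    total_layers: int,
    terminal: str | ResidueToken,
    *,
    id: str = "",
) -> PeptideSequence:
    """Test probe: the motif repeated from the surface up, capped by the
    terminal block coupled last; ``total_layers`` counts the terminal.

    motif (Ala, Gly), 3 layers, biotin → surface order Ala-Gly-biotin
    (a "3-mer"); 6 layers → Ala-Gly-Ala-Gly-Ala-biotin; 9 layers →
    Ala-Gly-Ala-Gly-Ala-Gly-Ala-Gly-biotin.
    """
    if total_layers < 1:
        raise SequenceError("total_layers must be >= 1")
    if not motif:
        raise SequenceError("motif must be non-empty")
    toks = [m if isinstance(m, ResidueToken) else ResidueToken(m) for m in motif]
    term = terminal if isinstance(terminal, ResidueToken) else ResidueToken(terminal)
    body = [toks[i % len(toks)] for i in range(total_layers - 1)]
    return PeptideSequence(tuple(body + [term]), id=id or f"probe{total_layers}")


def layer_blocks(library: Iterable[PeptideSequence]) -> dict[int, set[str]]:
    """Distinct building blocks needed per elongation layer.

    Layers count from the surface (C-terminus); shorter peptides are simply
    absent from later layers.  Drives the scheduler's donor counts.
    """
    blocks: dict[int, set[str]] = {}
    for seq in library:
        for i, res in enumerate(seq.residues, start=1):
            blocks.setdefault(i, set()).add(res.token)
    return blocks


# ---------------------------------------------------------------------------
# Library I/O
# ---------------------------------------------------------------------------

def write_library_tsv(
    library: Iterable[PeptideSequence], path: str | Path, *, header: str | None = None
) -> None:
    """Write ``id<TAB>sequence`` (N→C display) rows; optional comment header."""
    df = pd.DataFrame(
        {"id": [s.id for s in library], "sequence": [s.display for s in library]}
    )
    path = Path(path)
    with path.open("w") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> list[PeptideSequence]:
    """Read a library TSV written by :func:`write_library_tsv` (exact
    round-trip)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if not {"id", "sequence"} <= set(df.columns):
        raise SequenceError(f"{path}: expected columns 'id' and 'sequence'")
    return [
        parse_sequence(row.sequence, id=row.id) for row in df.itertuples(index=False)
    ]


def write_fasta(library: Iterable[PeptideSequence], path: str | Path) -> None:
    """FASTA export of canonical-only sequences (one-letter, N→C).

    Extended tokens have no one-letter form and are rejected.
    """
    lines = []
    for seq in library:
        bad = [r.token for r in seq.residues if not r.is_canonical]
        if bad:
            raise SequenceError(
                f"{seq.id or seq.display}: cannot export extended tokens "
                f"{bad} to FASTA"
            )
        letters = "".join(r.one_letter for r in reversed(seq.residues))
        lines.append(f">{seq.id or seq.display}\n{letters}\n")
    Path(path).write_text("".join(lines))
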