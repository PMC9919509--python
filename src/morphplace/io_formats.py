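"""Readers and writers for the file formats the pipeline touches.

Character matrices travel as NEXUS DATA/CHARACTERS blocks.  The dialect
accepted here is the one morphological supplements actually use: a STANDARD
matrix whose first few characters may be continuous ratios written as decimal
tokens (the discrete-coded fallback is accepted too), ``(01)``-style
polymorphisms, ``?`` for missing and ``-`` for inapplicable cells, and an
ASSUMPTIONS/TYPESET block flagging which multistate characters are ordered.
Trees travel as Newick (parsed with dendropy); reports as deterministic TSV.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import dendropy
import pandas as pd


class NexusFormatError(ValueError):
    """Raised when a NEXUS file violates the dialect this pipeline accepts."""


class _Sentinel:
    __slots__ = ("token",)

    def __init__(self, token: str):
        self.token = token

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<{self.token}>"


#: Cell scored as unknown ('?'): fully ambiguous downstream.
MISSING = _Sentinel("?")
#: Cell scored as inapplicable ('-'): stored distinctly, treated as fully
#: ambiguous in inference (the conventional treatment for gap-coded cells).
INAPPLICABLE = _Sentinel("-")

DiscreteCell = Union[frozenset, _Sentinel]
Cell = Union[frozenset, float, _Sentinel]


@dataclass(frozen=True)
class CharacterDefinition:
    """Metadata for one character, numbered 1-based as in anatomical lists."""

    char_id: int
    kind: str = "discrete"  # "discrete" | "continuous"
    n_states: int = 2
    ordered: bool = False
    label: str = ""
    state_labels: tuple = ()

    def __post_init__(self):
        if self.kind not in ("discrete", "continuous"):
            raise ValueError(f"char {self.char_id}: unknown kind {self.kind!r}")
        if self.kind == "discrete":
            if self.n_states < 2:
                raise ValueError(
                    f"char {self.char_id}: discrete characters need >= 2 states"
                )
            if self.ordered and self.n_states < 3:
                raise ValueError(
                    f"char {self.char_id}: ordering is meaningful only for >= 3 states"
                )
        elif self.ordered:
            raise ValueError(f"char {self.char_id}: continuous characters cannot be ordered")


@dataclass
class CharacterMatrix:
    """Taxa x characters grid of state sets / reals / MISSING / INAPPLICABLE."""

    taxa: list
    definitions: list
    cells: list  # cells[taxon_index][char_index]

    def __post_init__(self):
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise NexusFormatError(f"duplicate taxon name(s): {', '.join(dupes)}")
        ids = [d.char_id for d in self.definitions]
        if ids != list(range(1, len(ids) + 1)):
            raise NexusFormatError("character ids must be 1-based and contiguous")
        for taxon, row in zip(self.taxa, self.cells):
            if len(row) != len(self.definitions):
                raise NexusFormatError(
                    f"ragged matrix: taxon {taxon!r} has {len(row)} cells, "
                    f"expected {len(self.definitions)}"
                )
            for d, cell in zip(self.definitions, row):
                self._validate_cell(taxon, d, cell)

    @staticmethod
    def _validate_cell(taxon: str, d: CharacterDefinition, cell: Cell) -> None:
        if cell is MISSING or cell is INAPPLICABLE:
            if cell is INAPPLICABLE and d.kind == "continuous":
                raise NexusFormatError(
                    f"taxon {taxon!r}, char {d.char_id}: continuous cells cannot be "
                    "inapplicable (use MISSING)"
                )
            return
        if d.kind == "continuous":
            if not isinstance(cell, float) or cell != cell or cell in (float("inf"), float("-inf")):
                raise NexusFormatError(
                    f"taxon {taxon!r}, char {d.char_id}: continuous cell must be a "
                    f"finite real, got {cell!r}"
                )
            return
        if not isinstance(cell, frozenset) or not cell:
            raise NexusFormatError(
                f"taxon {taxon!r}, char {d.char_id}: discrete cell must be a "
                f"non-empty state set, got {cell!r}"
            )
        bad = [s for s in cell if not (0 <= s < d.n_states)]
        if bad:
            raise NexusFormatError(
                f"taxon {taxon!r}, char {d.char_id}: state code(s) {bad} out of "
                f"range 0..{d.n_states - 1}"
            )

    # -- convenience -----------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_chars(self) -> int:
        return len(self.definitions)

    def taxon_index(self, name: str) -> int:
        try:
            return self.taxa.index(name)
        except ValueError:
            raise KeyError(f"taxon {name!r} not in matrix") from None

    def definition(self, char_id: int) -> CharacterDefinition:
        if not 1 <= char_id <= self.n_chars:
            raise KeyError(f"char {char_id} out of range 1..{self.n_chars}")
        return self.definitions[char_id - 1]

    def column(self, char_id: int) -> dict:
        """Map taxon name -> cell for one character (1-based id)."""
        j = char_id - 1
        self.definition(char_id)
        return {t: self.cells[i][j] for i, t in enumerate(self.taxa)}

    def row(self, taxon: str) -> list:
        return list(self.cells[self.taxon_index(taxon)])

    def discrete_char_ids(self) -> list:
        return [d.char_id for d in self.definitions if d.kind == "discrete"]

    def continuous_char_ids(self) -> list:
        return [d.char_id for d in self.definitions if d.kind == "continuous"]

    def subset_taxa(self, keep: Iterable) -> "CharacterMatrix":
        keep = list(keep)
        idx = [self.taxon_index(t) for t in keep]
        return CharacterMatrix(
            taxa=keep,
            definitions=list(self.definitions),
            cells=[list(self.cells[i]) for i in idx],
        )


# ---------------------------------------------------------------------------
# NEXUS parsing
# ---------------------------------------------------------------------------

_FLOAT_RE = re.compile(r"[+-]?(\d+\.\d*|\.\d+|\d+[eE][+-]?\d+|\d+\.\d*[eE][+-]?\d+)$")


def _strip_nexus_comments(text: str) -> str:
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]":
            if depth == 0:
                raise NexusFormatError("unbalanced ']' comment delimiter")
            depth -= 1
        elif depth == 0:
            out.append(ch)
    if depth:
        raise NexusFormatError("unterminated '[' comment")
    return "".join(out)


def _split_commands(block_body: str) -> list:
    return [c.strip() for c in block_body.split(";") if c.strip()]


def _find_blocks(text: str) -> list:
    """Return (name, body) for each BEGIN ...; ... END; block."""
    blocks = []
    for m in re.finditer(
        r"begin\s+(\w+)\s*;(.*?)\bend\s*;", text, re.IGNORECASE | re.DOTALL
    ):
        blocks.append((m.group(1).lower(), m.group(2)))
    return blocks


def _parse_ranges(spec: str, n: int) -> list:
    """Parse a NEXUS character list like '1-5 7 9-10' into 1-based ids."""
    ids = []
    for tok in spec.replace(",", " ").split():
        if "-" in tok and not tok.startswith("-"):
            a, b = tok.split("-", 1)
            b = n if b.strip() == "." else int(b)
            ids.extend(range(int(a), b + 1))
        else:
            ids.append(int(tok))
    bad = [i for i in ids if not 1 <= i <= n]
    if bad:
        raise NexusFormatError(f"character list {spec!r} out of range 1..{n}")
    return ids


def _tokenise_row(row: str, missing: str, gap: str, taxon: str) -> list:
    """Split one matrix row into cell tokens.

    Whitespace-separated decimal tokens are continuous cells; everything else
    is a run of single-symbol discrete cells with ``(...)``/``{...}`` groups.
    """
    cells = []
    for chunk in row.split():
        if _FLOAT_RE.match(chunk):
            cells.append(("cont", float(chunk)))
            continue
        i = 0
        while i < len(chunk):
            ch = chunk[i]
            if ch in "({":
                close = ")" if ch == "(" else "}"
                j = chunk.find(close, i + 1)
                if j < 0:
                    raise NexusFormatError(
                        f"taxon {taxon!r}: unterminated polymorphism group in row"
                    )
                group = chunk[i + 1 : j].replace(",", "").replace(" ", "")
                if len(group) < 2:
                    raise NexusFormatError(
                        f"taxon {taxon!r}: polymorphic cell needs >= 2 states"
                    )
                cells.append(("poly", group))
                i = j + 1
            elif ch == missing:
                cells.append(("missing", None))
                i += 1
            elif ch == gap:
                cells.append(("gap", None))
                i += 1
            else:
                cells.append(("sym", ch))
                i += 1
    return cells


def read_nexus(path) -> CharacterMatrix:
    """Read a NEXUS character matrix (see module docstring for the dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = _strip_nexus_comments(path.read_text())
    if not text.lstrip().lower().startswith("#nexus"):
        raise NexusFormatError(f"{path}: missing #NEXUS header")
    blocks = _find_blocks(text)
    data_blocks = [b for n, b in blocks if n in ("data", "characters")]
    if not data_blocks:
        raise NexusFormatError(f"{path}: no DATA or CHARACTERS block")
    body = data_blocks[0]

    symbols = "0123456789"
    missing_tok, gap_tok = "?", "-"
    nchar = ntax = None
    matrix_cmd = None
    for cmd in _split_commands(body):
        head = cmd.split(None, 1)[0].lower()
        if head == "dimensions":
            m = re.search(r"nchar\s*=\s*(\d+)", cmd, re.IGNORECASE)
            if m:
                nchar = int(m.group(1))
            m = re.search(r"ntax\s*=\s*(\d+)", cmd, re.IGNORECASE)
            if m:
                ntax = int(m.group(1))
        elif head == "format":
            m = re.search(r'symbols\s*=\s*"([^"]*)"', cmd, re.IGNORECASE)
            if m:
                symbols = m.group(1).replace(" ", "")
            m = re.search(r"missing\s*=\s*(\S)", cmd, re.IGNORECASE)
            if m:
                missing_tok = m.group(1)
            m = re.search(r"gap\s*=\s*(\S)", cmd, re.IGNORECASE)
            if m:
                gap_tok = m.group(1)
            if re.search(r"interleave(?!\s*=\s*no)", cmd, re.IGNORECASE):
                raise NexusFormatError(f"{path}: interleaved matrices not supported")
        elif head == "matrix":
            matrix_cmd = cmd[len("matrix"):].strip()
    if matrix_cmd is None:
        raise NexusFormatError(f"{path}: DATA block has no MATRIX command")
    if nchar is None:
        raise NexusFormatError(f"{path}: DIMENSIONS NCHAR missing")

    sym_code = {s: i for i, s in enumerate(symbols)}

    taxa, raw_rows = [], []
    for line in matrix_cmd.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("'"):
            j = line.find("'", 1)
            if j < 0:
                raise NexusFormatError(f"{path}: unterminated quoted taxon name")
            taxon, rest = line[1:j], line[j + 1 :]
        else:
            parts = line.split(None, 1)
            if len(parts) != 2:
                raise NexusFormatError(f"{path}: matrix row {line!r} has no data")
            taxon, rest = parts
        if taxon in taxa:
            raise NexusFormatError(f"{path}: duplicate taxon {taxon!r}")
        taxa.append(taxon)
        raw_rows.append(_tokenise_row(rest, missing_tok, gap_tok, taxon))

    if ntax is not None and len(taxa) != ntax:
        raise NexusFormatError(
            f"{path}: DIMENSIONS NTAX={ntax} but {len(taxa)} rows present"
        )
    for taxon, row in zip(taxa, raw_rows):
        if len(row) != nchar:
            raise NexusFormatError(
                f"{path}: ragged row for taxon {taxon!r}: {len(row)} cells, "
                f"expected {nchar}"
            )

    # ASSUMPTIONS: ordered typeset and an optional explicit continuous charset
    ordered_ids: set = set()
    continuous_ids: set = set()
    for name, abody in blocks:
        if name not in ("assumptions", "sets"):
            continue
        for cmd in _split_commands(abody):
            head = cmd.split(None, 1)[0].lower()
            if head == "typeset":
                m = re.search(r"=(.*)", cmd, re.DOTALL)
                if not m:
                    continue
                for part in m.group(1).split(","):
                    if ":" not in part:
                        continue
                    tname, clist = part.split(":", 1)
                    if tname.strip().lower() in ("ord", "ordered"):
                        ordered_ids.update(_parse_ranges(clist, nchar))
            elif head == "charset":
                m = re.match(r"charset\s+(\S+)\s*=(.*)", cmd, re.IGNORECASE | re.DOTALL)
                if m and m.group(1).lower().startswith("continuous"):
                    continuous_ids.update(_parse_ranges(m.group(2), nchar))

    # infer per-character kind/state count from the cells
    definitions, cells = [], [[None] * nchar for _ in taxa]
    for j in range(nchar):
        col = [row[j] for row in raw_rows]
        kinds = {k for k, _ in col}
        is_cont = (j + 1) in continuous_ids or "cont" in kinds
        if is_cont:
            if "sym" in kinds or "poly" in kinds or "gap" in kinds:
                if "cont" in kinds:
                    raise NexusFormatError(
                        f"{path}: char {j + 1} mixes continuous and discrete cells"
                    )
                # declared-continuous but discrete-coded: fallback to discrete
                is_cont = False
        if is_cont:
            for i, (k, v) in enumerate(col):
                cells[i][j] = float(v) if k == "cont" else MISSING
            definitions.append(
                CharacterDefinition(char_id=j + 1, kind="continuous", n_states=0)
            )
            continue
        observed = set()
        for i, (k, v) in enumerate(col):
            if k == "sym":
                if v not in sym_code:
                    raise NexusFormatError(
                        f"{path}: char {j + 1}: symbol {v!r} not in declared "
                        f"symbols {symbols!r}"
                    )
                cells[i][j] = frozenset({sym_code[v]})
            elif k == "poly":
                states = set()
                for ch in v:
                    if ch not in sym_code:
                        raise NexusFormatError(
                            f"{path}: char {j + 1}: symbol {ch!r} not in declared "
                            f"symbols {symbols!r}"
                        )
                    states.add(sym_code[ch])
                cells[i][j] = frozenset(states)
            elif k == "missing":
                cells[i][j] = MISSING
            else:
                cells[i][j] = INAPPLICABLE
            if isinstance(cells[i][j], frozenset):
                observed |= cells[i][j]
        n_states = max(2, (max(observed) + 1) if observed else 2)
        if (j + 1) in ordered_ids:
            n_states = max(n_states, 3)  # ordering implies >= 3 states
        ordered = (j + 1) in ordered_ids
        definitions.append(
            CharacterDefinition(char_id=j + 1, kind="discrete", n_states=n_states,
                                ordered=ordered)
        )
    return CharacterMatrix(taxa=taxa, definitions=definitions, cells=cells)


def write_nexus(matrix: CharacterMatrix, path) -> None:
    """Write a matrix in the dialect read_nexus accepts (round-trip safe)."""
    path = Path(path)
    max_states = max(
        [d.n_states for d in matrix.definitions if d.kind == "discrete"], default=2
    )
    symbols = "0123456789"[:max_states]
    name_w = max((len(t) for t in matrix.taxa), default=1) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"  DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_chars};",
        f'  FORMAT DATATYPE=STANDARD SYMBOLS="{symbols}" MISSING=? GAP=-;',
        "  MATRIX",
    ]
    for taxon, row in zip(matrix.taxa, matrix.cells):
        name = taxon if re.fullmatch(r"[\w.]+", taxon) else f"'{taxon}'"
        toks = []
        for d, cell in zip(matrix.definitions, row):
            if d.kind == "continuous":
                toks.append("?" if cell is MISSING else repr(float(cell)))
            elif cell is MISSING:
                toks.append("?")
            elif cell is INAPPLICABLE:
                toks.append("-")
            elif len(cell) == 1:
                toks.append(symbols[next(iter(cell))])
            else:
                toks.append("(" + "".join(symbols[s] for s in sorted(cell)) + ")")
        lines.append(f"    {name:<{name_w}}" + " ".join(toks))
    lines += ["  ;", "END;"]
    ordered = [d.char_id for d in matrix.definitions if d.ordered]
    continuous = matrix.continuous_char_ids()
    if ordered or continuous:
        lines.append("BEGIN ASSUMPTIONS;")
        if ordered:
            lines.append(
                "  TYPESET * default = ord: "
                + " ".join(str(i) for i in ordered) + ";"
            )
        if continuous:
            lines.append(
                "  CHARSET continuous = "
                + " ".join(str(i) for i in continuous) + ";"
            )
        lines.append("END;")
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(source) -> dendropy.Tree:
    """Read a rooted Newick tree from a path or string; labels must be unique."""
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        data = Path(source).read_text()
    else:
        data = str(source)
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", rooting="force-rooted",
            suppress_internal_node_taxa=True, preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValueError(f"Newick parse error: {exc}") from exc
    labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    dupes = sorted({l for l in labels if labels.count(l) > 1})
    if dupes:
        raise ValueError(f"duplicate tip label(s): {', '.join(dupes)}")
    return tree


def write_newick(tree: dendropy.Tree, path=None) -> str:
    s = tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        Path(path).write_text(s + "\n")
    return s


# ---------------------------------------------------------------------------
# Reports and clade tables
# ---------------------------------------------------------------------------

def _record_to_dict(rec) -> dict:
    if dataclasses.is_dataclass(rec):
        d = dataclasses.asdict(rec)
    elif isinstance(rec, dict):
        d = dict(rec)
    else:
        raise TypeError(f"cannot serialise record of type {type(rec).__name__}")
    out = {}
    for k, v in d.items():
        if isinstance(v, (frozenset, set)):
            v = ",".join(str(x) for x in sorted(v))
        elif isinstance(v, (list, tuple)):
            v = ",".join(str(x) for x in v)
        elif isinstance(v, dict):
            v = ";".join(f"{kk}={vv}" for kk, vv in sorted(v.items(), key=lambda p: str(p[0])))
        out[k] = v
    return out


def write_report(records: Sequence, path) -> None:
    """Write records as a deterministic, sorted TSV (byte-stable across calls)."""
    records = list(records)
    if not records:
        raise ValueError("refusing to write an empty report")
    rows = [_record_to_dict(r) for r in records]
    df = pd.DataFrame(rows)
    df = df.sort_values(by=list(df.columns), kind="mergesort").reset_index(drop=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_clade_table(path) -> list:
    """Read clade definitions from JSON: [{name, concept, tips: [...]}, ...]."""
    import json

    from .scaffold import CladeDefinition

    raw = json.loads(Path(path).read_text())
    return [
        CladeDefinition(
            name=e["name"],
            tips=frozenset(e["tips"]),
            concept=e.get("concept", "crown"),
        )
        for e in raw
    ]


def write_clade_table(clades: Sequence, path) -> None:
    import json

    payload = [
        {"name": c.name, "concept": c.concept, "tips": sorted(c.tips)} for c in clades
    ]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
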