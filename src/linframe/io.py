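"""Edge-list and parameter-file input/output.

Edge lists are TSV with columns ``source  target  label``; ``#`` starts a
comment and blank lines are ignored.  Labels follow the grammar
``IDENT ('*' IDENT)*`` or a positive decimal literal.  Vertex names are
arbitrary non-whitespace strings.  Writing produces a canonical sorted row
order, so write-then-read round-trips exactly.

Parameter files hold one ``name value`` pair per line (``=`` or whitespace
separated); every symbol a computation needs must be present — nothing is
defaulted.
"""

from __future__ import annotations

from pathlib import Path

from .graph import LabeledDigraph, LabelExpr, build_graph

__all__ = ["read_edge_list", "write_edge_list", "read_params"]


def read_edge_list(path: str | Path) -> LabeledDigraph:
    records = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'source target label', got {raw!r}")
        try:
            LabelExpr.parse(parts[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        records.append((parts[0], parts[1], parts[2]))
    try:
        return build_graph(records)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_edge_list(G: LabeledDigraph, path: str | Path) -> None:
    rows = sorted((s, t, str(label)) for s, t, label in G.edges())
    text = "\n".join("\t".join(row) for row in rows)
    Path(path).write_text(text + "\n")


def read_params(path: str | Path) -> dict[str, float]:
    out: dict[str, float] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        parts = line.replace("=", " ").split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'name value', got {raw!r}")
        name, value_text = parts
        value = float(value_text)
        if value <= 0:
            raise ValueError(f"{path}:{lineno}: labels must be positive: {name} = {value}")
        out[name] = value
    return out
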