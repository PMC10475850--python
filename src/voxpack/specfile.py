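"""Design specification ("spec file") parsing.

The dialect is flat ``key = value`` lines with ``#`` comments.  Positions
are written ``chain:resnum`` or ``chain:resnum:wt_aa`` (one-letter code);
mutable entries append the allowed target amino acids as a one-letter
string: ``A:12:L:AILMV``.  Multiple entries are separated by ``;``.

Recognized keys: mut_res, rpk_res, scramble_order, m_mutations, n_paths,
n_iters, w_pp, w_k, w_lj, w_solv, w_elec, max_lj, seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .constants import DEFAULT_MAX_LJ
from .engine import Weights
from .params import ONE_TO_THREE


class SpecError(ValueError):
    pass


@dataclass(frozen=True)
class Position:
    chain: str
    resnum: int
    wt_aa: str | None = None  #: one-letter, optional sanity check

    def __str__(self):
        tail = f":{self.wt_aa}" if self.wt_aa else ""
        return f"{self.chain}:{self.resnum}{tail}"


@dataclass
class DesignSpec:
    """Sampler configuration for combinatorial design."""

    mut_res: list[tuple[Position, list[str]]] = field(default_factory=list)
    rpk_res: list[Position] = field(default_factory=list)
    scramble_order: bool = False
    m_mutations: int = 3
    n_paths: int = 5
    n_iters: int = 1
    weights: Weights = field(default_factory=Weights)
    max_lj: float = DEFAULT_MAX_LJ
    random_seed: int = 0

    def __post_init__(self):
        if self.m_mutations < 1 or self.n_paths < 1 or self.n_iters < 1:
            raise SpecError("m_mutations, n_paths and n_iters must be >= 1")
        mut_keys = {(p.chain, p.resnum) for p, _ in self.mut_res}
        rpk_keys = {(p.chain, p.resnum) for p in self.rpk_res}
        overlap = mut_keys & rpk_keys
        if overlap:
            raise SpecError(f"positions both mutable and repackable: {overlap}")

    def resolve(self, structure) -> tuple[list[tuple[int, list[str]]], list[int]]:
        """Map author-numbered positions to 0-based residue indices."""
        index = {(r.chain, r.seq_id): i for i, r in enumerate(structure.residues)}

        def look(pos: Position) -> int:
            try:
                i = index[(pos.chain, pos.resnum)]
            except KeyError:
                raise SpecError(f"position {pos} not found in structure") from None
            if pos.wt_aa:
                want = ONE_TO_THREE.get(pos.wt_aa.upper())
                if structure[i].name != want:
                    raise SpecError(
                        f"position {pos}: structure has {structure[i].name}")
            return i

        mut = [(look(p), aas) for p, aas in self.mut_res]
        rpk = [look(p) for p in self.rpk_res]
        return mut, rpk


def _parse_position(tok: str, lineno: int) -> tuple[Position, list[str]]:
    parts = tok.strip().split(":")
    if len(parts) < 2 or len(parts) > 4:
        raise SpecError(f"line {lineno}: malformed position {tok!r}")
    chain = parts[0].strip()
    try:
        resnum = int(parts[1])
    except ValueError:
        raise SpecError(f"line {lineno}: bad residue number in {tok!r}") from None
    wt = None
    targets: list[str] = []
    if len(parts) >= 3 and parts[2].strip():
        wt = parts[2].strip().upper()
        if wt not in ONE_TO_THREE:
            raise SpecError(f"line {lineno}: unknown wild-type code {wt!r}")
    if len(parts) == 4:
        for c in parts[3].strip().upper():
            if c not in ONE_TO_THREE:
                raise SpecError(f"line {lineno}: unknown target code {c!r}")
            targets.append(ONE_TO_THREE[c])
    return Position(chain, resnum, wt), targets


_BOOL = {"true": True, "1": True, "yes": True,
         "false": False, "0": False, "no": False}


def parse_design_spec(path: str | Path) -> DesignSpec:
    """Parse a spec file; unknown keys and malformed positions are errors."""
    kw: dict = {}
    wkw: dict = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise SpecError(f"line {lineno}: expected 'key = value'")
            key, val = (s.strip() for s in line.split("=", 1))
            key = key.lstrip("-")
            if key == "mut_res":
                kw["mut_res"] = []
                for tok in filter(None, (t.strip() for t in val.split(";"))):
                    pos, targets = _parse_position(tok, lineno)
                    if not targets:
                        raise SpecError(
                            f"line {lineno}: mutable position {tok!r} lists "
                            "no target amino acids")
                    kw["mut_res"].append((pos, targets))
            elif key == "rpk_res":
                kw["rpk_res"] = [
                    _parse_position(tok, lineno)[0]
                    for tok in filter(None, (t.strip() for t in val.split(";")))]
            elif key == "scramble_order":
                try:
                    kw["scramble_order"] = _BOOL[val.lower()]
                except KeyError:
                    raise SpecError(f"line {lineno}: bad boolean {val!r}") from None
            elif key in ("m_mutations", "n_paths", "n_iters", "seed"):
                try:
                    kw["random_seed" if key == "seed" else key] = int(val)
                except ValueError:
                    raise SpecError(f"line {lineno}: bad integer {val!r}") from None
            elif key in ("w_pp", "w_k", "w_lj", "w_solv", "w_elec"):
                wkw[key] = float(val)
            elif key == "max_lj":
                kw["max_lj"] = float(val)
            else:
                raise SpecError(f"line {lineno}: unknown key {key!r}")
    kw["weights"] = Weights(**wkw)
    return DesignSpec(**kw)
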