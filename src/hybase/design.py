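"""Cross designs for F1 hybrid experiments.

A :class:`TrioDesign` names one cross: the maternal parent, the paternal
parent, the F1 sample, and optionally the reciprocal cross in which the two
parents swap roles. Reciprocal pairs are what make genotype-dependent versus
parent-of-origin allelic expression distinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class TrioDesign:
    """One parent–parent–F1 trio.

    Parameters
    ----------
    cross_id : str
        Identifier for the cross, e.g. ``"GLxTQ"``.
    maternal : str
        Identifier of the maternal (seed) parent.
    paternal : str
        Identifier of the pollen parent.
    f1_id : str
        Sample identifier of the F1 hybrid. Defaults to ``cross_id``.
    reciprocal_id : str or None
        ``cross_id`` of the reciprocal cross, if one exists in the design.
    """

    cross_id: str
    maternal: str
    paternal: str
    f1_id: str = ""
    reciprocal_id: str | None = None

    def __post_init__(self) -> None:
        if self.maternal == self.paternal:
            raise ValueError(
                f"cross {self.cross_id!r}: maternal and paternal parents are "
                f"identical ({self.maternal!r}); a selfed line has no "
                "discriminating SNPs"
            )
        if not self.f1_id:
            object.__setattr__(self, "f1_id", self.cross_id)

    @property
    def parents(self) -> frozenset[str]:
        return frozenset((self.maternal, self.paternal))

    def is_reciprocal_of(self, other: "TrioDesign") -> bool:
        """True when *other* is the same pair of parents with roles swapped."""
        return (
            self.maternal == other.paternal
            and self.paternal == other.maternal
        )

    def parent_role(self, parent: str) -> str:
        if parent == self.maternal:
            return "maternal"
        if parent == self.paternal:
            return "paternal"
        raise KeyError(f"{parent!r} is not a parent of cross {self.cross_id!r}")


#: The three indica varieties used throughout the examples: Guangluai #4 (GL),
#: Teqing (TQ) and 93-11. Two crosses show high biomass heterosis (GLxTQ,
#: GLx9311) and one low (9311xTQ).
DEFAULT_PARENTS = ("GL", "TQ", "9311")


def default_designs(reciprocal: bool = True) -> list[TrioDesign]:
    """Build the standard three-cross design (optionally with reciprocals)."""
    pairs = [("GL", "TQ"), ("GL", "9311"), ("9311", "TQ")]
    designs: list[TrioDesign] = []
    for mat, pat in pairs:
        fwd = f"{mat}x{pat}"
        rev = f"{pat}x{mat}"
        designs.append(
            TrioDesign(fwd, mat, pat, reciprocal_id=rev if reciprocal else None)
        )
        if reciprocal:
            designs.append(TrioDesign(rev, pat, mat, reciprocal_id=fwd))
    return designs


def reciprocal_pairs(designs: list[TrioDesign]) -> list[tuple[TrioDesign, TrioDesign]]:
    """Return (forward, reciprocal) pairs present in *designs*, each pair once."""
    by_id = {d.cross_id: d for d in designs}
    pairs = []
    seen: set[str] = set()
    for d in designs:
        if d.cross_id in seen or not d.reciprocal_id:
            continue
        other = by_id.get(d.reciprocal_id)
        if other is None:
            continue
        if not d.is_reciprocal_of(other):
            raise ValueError(
                f"{d.cross_id} declares reciprocal {other.cross_id} but parent "
                "roles do not swap"
            )
        seen.update((d.cross_id, other.cross_id))
        pairs.append((d, other))
    return pairs
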