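"""RNA secondary-structure prediction behind a pluggable backend contract.

The real backend wraps the ViennaRNA programming interface configured the
way hairpin impact prediction needs it: minimum-free-energy (MFE)
structure, partition function, maximum-expected-accuracy (MEA) and
centroid structures, with dangling-end energies added on both sides of
each helix (the ``-d2`` convention). A mock backend returns
caller-specified structures verbatim so that every downstream module can
be tested bit-exactly without a thermodynamic library.

Energies are kcal/mol; structures are dot-bracket strings of the same
length as the sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "FoldResult",
    "ViennaRNAFold",
    "MockFold",
    "mock_fold_result",
    "pair_status",
]

_ALPHABET = frozenset("ACGUN")


@dataclass(frozen=True)
class FoldResult:
    """Structures and energies for one RNA sequence.

    ``mfe_frequency`` is the Boltzmann probability of the MFE structure
    within the thermodynamic ensemble. ``mea_energy`` and
    ``centroid_energy`` are the free energies of those structures
    evaluated on the same energy model, so ``mfe_energy`` is a lower
    bound for both.
    """

    sequence: str
    mfe_structure: str
    mfe_energy: float
    mea_structure: str
    mea_energy: float
    centroid_structure: str
    centroid_energy: float
    mfe_frequency: float

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for name in ("mfe_structure", "mea_structure", "centroid_structure"):
            s = getattr(self, name)
            if len(s) != n:
                raise ValueError(f"{name} length {len(s)} != sequence length {n}")
            depth = 0
            for c in s:
                if c == "(":
                    depth += 1
                elif c == ")":
                    depth -= 1
                    if depth < 0:
                        raise ValueError(f"{name} is not balanced: {s!r}")
                elif c != ".":
                    raise ValueError(f"{name} contains {c!r}")
            if depth != 0:
                raise ValueError(f"{name} is not balanced: {s!r}")
        if not (0.0 < self.mfe_frequency <= 1.0):
            raise ValueError(f"mfe_frequency {self.mfe_frequency} outside (0, 1]")

    def structure(self, representation: str) -> str:
        return getattr(self, f"{_REP_ATTR[representation]}_structure")

    def energy(self, representation: str) -> float:
        return getattr(self, f"{_REP_ATTR[representation]}_energy")


_REP_ATTR = {"MFE": "mfe", "MEA": "mea", "CEN": "centroid"}

#: Structure representations reported throughout the package, in output order.
REPRESENTATIONS = ("CEN", "MEA", "MFE")


def _check_sequence(sequence: str) -> str:
    if not sequence:
        raise ValueError("cannot fold an empty sequence")
    seq = sequence.upper().replace("T", "U")
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(f"sequence contains invalid characters {sorted(bad)}")
    return seq


def pair_status(structure: str) -> list[bool]:
    """Per-position paired flags: True iff the base is in a helix."""
    return [c in "()" for c in structure]


class ViennaRNAFold:
    """Thermodynamic backend (ViennaRNA).

    Configuration: partition function on, MEA and centroid computed from
    it, dangles on both sides (model default ``dangles=2``). Results are
    memoised per sequence because the analysis pipeline refolds the same
    wild-type and bare-hairpin sequences for every nearby variant.
    """

    name = "ViennaRNA"

    def __init__(self) -> None:
        import RNA  # deferred so the mock backend works without the library

        self._rna = RNA
        self.version: str = RNA.__version__
        self._cache: dict[str, FoldResult] = {}

    def fold(self, sequence: str) -> FoldResult:
        seq = _check_sequence(sequence)
        hit = self._cache.get(seq)
        if hit is not None:
            return hit
        RNA = self._rna
        md = RNA.md()
        md.dangles = 2
        fc = RNA.fold_compound(seq, md)
        mfe_structure, mfe_energy = fc.mfe()
        fc.exp_params_rescale(mfe_energy)
        fc.pf()
        centroid_structure, _ = fc.centroid()
        mea_structure, _ = fc.MEA()
        frequency = fc.pr_structure(mfe_structure)
        # an open chain has probability rounding hazards; keep the contract
        frequency = min(max(frequency, 1e-300), 1.0)
        result = FoldResult(
            sequence=seq,
            mfe_structure=mfe_structure,
            mfe_energy=mfe_energy,
            mea_structure=mea_structure,
            mea_energy=fc.eval_structure(mea_structure),
            centroid_structure=centroid_structure,
            centroid_energy=fc.eval_structure(centroid_structure),
            mfe_frequency=frequency,
        )
        self._cache[seq] = result
        return result


def mock_fold_result(
    sequence: str,
    mfe: str,
    mea: str | None = None,
    centroid: str | None = None,
    mfe_energy: float = -10.0,
    mea_energy: float | None = None,
    centroid_energy: float | None = None,
    mfe_frequency: float = 0.5,
) -> FoldResult:
    """Build a FoldResult from explicit structures (tests, fixtures)."""
    seq = _check_sequence(sequence)
    mea = mfe if mea is None else mea
    centroid = mfe if centroid is None else centroid
    return FoldResult(
        sequence=seq,
        mfe_structure=mfe,
        mfe_energy=mfe_energy,
        mea_structure=mea,
        mea_energy=mfe_energy if mea_energy is None else mea_energy,
        centroid_structure=centroid,
        centroid_energy=mfe_energy if centroid_energy is None else centroid_energy,
        mfe_frequency=mfe_frequency,
    )


class MockFold:
    """Injectable backend returning pre-registered results verbatim."""

    name = "mock"
    version = "0"

    def __init__(self, results: dict[str, FoldResult] | None = None) -> None:
        self._results: dict[str, FoldResult] = {}
        for res in (results or {}).values():
            self.add(res)

    def add(self, result: FoldResult) -> None:
        self._results[result.sequence] = result

    def fold(self, sequence: str) -> FoldResult:
        seq = _check_sequence(sequence)
        try:
            return self._results[seq]
        except KeyError:
            raise ValueError(f"mock backend has no result for {seq!r}") from None
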