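import pytest

from itsdiag import datasets
from itsdiag.alignment import AlignedMatrix

# Independent IUPAC table for oracle checks (typed out, not imported from
# the package under test).
IUPAC = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"G", "C"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"},
    "B": {"C", "G", "T"}, "D": {"A", "G", "T"},
    "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
}


@pytest.fixture(scope="session")
def sister_species_matrix() -> AlignedMatrix:
    """16 specimens of the two sister species with 21 variable positions."""
    return datasets.load_glabriusculus_badiosquamulosus()


@pytest.fixture(scope="session")
def dunensis_matrix() -> AlignedMatrix:
    return datasets.load_dunensis()


@pytest.fixture(scope="session")
def marker_demo_matrix() -> AlignedMatrix:
    return datasets.load_marker_demo()


def oracle_state(char: str, terminal: bool = False):
    """Oracle state model: None = missing, '-' = gap, else a base set."""
    if char == "N" or (char == "-" and terminal):
        return None
    if char == "-":
        return "-"
    return frozenset(IUPAC[char])


def oracle_disjoint(a, b) -> bool:
    if a is None or b is None:
        return False
    if a == "-" or b == "-":
        return (a == "-") != (b == "-")
    return not (a & b)


def terminal_mask(row: str) -> list[bool]:
    n = len(row)
    lead = n - len(row.lstrip("-"))
    trail = n - len(row.rstrip("-"))
    if lead == n:
        trail = 0
    return [i < lead or i >= n - trail for i in range(n)]
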