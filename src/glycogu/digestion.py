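"""In silico protease digestion and glycation-site enumeration.

Glycation happens on the intact protein, before digestion, at primary
amines: the protein N-terminal alpha-amine or lysine epsilon-amines. A
glycated lysine is no longer a trypsin substrate, so a glycated tryptic
peptide necessarily carries a missed cleavage at the modified K, and the
C-terminal K of a tryptic peptide can never be glycated (it was cleaved
after). These constraints drive both glycoform enumeration and site
assignment.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .masses import CANONICAL_RESIDUES


@dataclass(frozen=True)
class CleavageRule:
    """Protease specificity: cut C-terminal to ``cut_after`` residues.

    ``proline_exception`` suppresses cleavage when the following residue is
    proline (the Keil rule); standard for trypsin.
    """

    name: str
    cut_after: frozenset[str]
    proline_exception: bool = False

    def __post_init__(self) -> None:
        if not self.cut_after:
            raise ValueError("cut_after must be non-empty")

    def cut_sites(self, sequence: str) -> list[int]:
        """0-based indices i such that the bond after sequence[i] is cleaved.

        The C-terminal residue is never a cut site (nothing follows it).
        """
        sites = []
        for i in range(len(sequence) - 1):
            if sequence[i] in self.cut_after:
                if self.proline_exception and sequence[i + 1] == "P":
                    continue
                sites.append(i)
        return sites


TRYPSIN = CleavageRule("trypsin", frozenset("KR"), proline_exception=True)
GLU_C = CleavageRule("glu-c", frozenset("DE"), proline_exception=False)

PRESET_RULES = {"trypsin": TRYPSIN, "glu-c": GLU_C}

PROTEIN_N_TERMINUS = "protein-n-terminus"


@dataclass(frozen=True)
class Peptide:
    """A proteolytic peptide with 1-based inclusive protein coordinates."""

    sequence: str
    protein_id: str
    start: int
    end: int
    missed_cleavages: int
    is_protein_nterm: bool

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("coordinates inconsistent with sequence length")
        if self.is_protein_nterm != (self.start == 1):
            raise ValueError("is_protein_nterm must hold exactly when start == 1")


@dataclass(frozen=True)
class GlycationSite:
    """Either a lysine site (1-based position within the peptide) or the
    protein N-terminus."""

    kind: str  # "lysine" | "protein-n-terminus"
    position: int | None = None  # 1-based within peptide; None for N-terminus

    def __post_init__(self) -> None:
        if self.kind not in ("lysine", PROTEIN_N_TERMINUS):
            raise ValueError(f"unknown site kind {self.kind!r}")
        if (self.kind == "lysine") != (self.position is not None):
            raise ValueError("lysine sites need a position; terminal sites do not")

    def __str__(self) -> str:
        return f"K{self.position}" if self.kind == "lysine" else "protein-N-term"


@dataclass(frozen=True)
class Glycoform:
    peptide: Peptide
    sites: tuple[GlycationSite, ...]

    def __post_init__(self) -> None:
        if not self.sites:
            raise ValueError("a glycoform carries at least one site")
        for site in self.sites:
            if site.kind == "lysine":
                if self.peptide.sequence[site.position - 1] != "K":
                    raise ValueError(f"site {site} does not point at a lysine")
            elif not self.peptide.is_protein_nterm:
                raise ValueError(
                    "protein-N-terminal glycation requires a protein-N-terminal peptide"
                )

    @property
    def n_glycations(self) -> int:
        return len(self.sites)


@dataclass(frozen=True)
class SiteAssignment:
    verdict: str  # "lysine" | "protein-n-terminus" | "ambiguous" | "inconsistent"
    rationale: str


def digest(protein, rule: CleavageRule, max_missed: int = 0) -> list[Peptide]:
    """Enumerate peptides with 0..max_missed missed cleavages.

    Returned peptides are ordered by start position then length; the
    zero-missed-cleavage peptides tile the protein exactly.
    """
    if max_missed < 0:
        raise ValueError("max_missed must be non-negative")
    if max_missed > 5:
        raise ValueError("max_missed ceiling is 5")
    seq = protein.sequence
    bad = sorted(set(seq) - CANONICAL_RESIDUES)
    if bad:
        raise ValueError(f"non-canonical residue(s) {bad} in {protein.id}")
    cuts = rule.cut_sites(seq)
    # fragment boundaries: 0-based [begin, stop) half-open
    edges = [0] + [c + 1 for c in cuts] + [len(seq)]
    peptides = []
    n_frag = len(edges) - 1
    for i in range(n_frag):
        for m in range(max_missed + 1):
            j = i + m + 1
            if j > n_frag:
                break
            begin, stop = edges[i], edges[j]
            peptides.append(
                Peptide(
                    sequence=seq[begin:stop],
                    protein_id=protein.id,
                    start=begin + 1,
                    end=stop,
                    missed_cleavages=m,
                    is_protein_nterm=begin == 0,
                )
            )
    peptides.sort(key=lambda p: (p.start, p.end - p.start))
    return peptides


def _candidate_sites(peptide: Peptide, rule: CleavageRule) -> list[GlycationSite]:
    """Admissible glycation sites for a peptide under a cleavage rule.

    For trypsin, a glycated K must be an uncleaved (missed) site: internal
    K positions that the rule would otherwise cut. The peptide's C-terminal
    K is excluded. For proteases that do not cut at K (e.g. Glu-C), every K
    is admissible. The protein N-terminus is a site only for the protein's
    first peptide.
    """
    sites: list[GlycationSite] = []
    if peptide.is_protein_nterm:
        sites.append(GlycationSite(PROTEIN_N_TERMINUS))
    k_is_cleaved = "K" in rule.cut_after
    for i, residue in enumerate(peptide.sequence):
        if residue != "K":
            continue
        pos = i + 1
        if k_is_cleaved:
            # must coincide with a suppressed (missed) cleavage: internal,
            # and an actual cut site under the rule (Keil KP bonds are not
            # cleavage sites, so glycation there leaves no missed-cleavage
            # signature and the K is not a candidate).
            if pos == len(peptide.sequence):
                continue
            if rule.proline_exception and peptide.sequence[i + 1] == "P":
                continue
        sites.append(GlycationSite("lysine", pos))
    return sites


def enumerate_glycoforms(
    peptide: Peptide, rule: CleavageRule, max_glycations: int = 1
) -> list[Glycoform]:
    """All glycoforms with 1..max_glycations admissible sites."""
    if max_glycations < 1:
        raise ValueError("max_glycations must be a positive integer")
    sites = _candidate_sites(peptide, rule)
    forms = []
    for n in range(1, max_glycations + 1):
        for combo in combinations(sites, n):
            forms.append(Glycoform(peptide, tuple(combo)))
    return forms


def assign_site(glycoform: Glycoform, rule: CleavageRule = TRYPSIN) -> SiteAssignment:
    """Assign the glycation site class from digestion evidence.

    Lysine glycation is inferred from a missed-cleavage K; N-terminal
    glycation is only possible on the protein's original N-terminal peptide
    and is further supported when that peptide lacks an internal lysine.
    When both site classes are admissible the call is ambiguous.
    """
    peptide = glycoform.peptide
    candidates = _candidate_sites(peptide, rule)
    lysine_candidates = [s for s in candidates if s.kind == "lysine"]
    nterm_admissible = peptide.is_protein_nterm
    if lysine_candidates and not nterm_admissible:
        chosen = [s for s in glycoform.sites if s.kind == "lysine"] or lysine_candidates
        ks = ", ".join(str(s) for s in chosen)
        return SiteAssignment(
            "lysine",
            f"missed-cleavage lysine ({ks}); peptide is not protein-N-terminal",
        )
    if nterm_admissible and not lysine_candidates:
        return SiteAssignment(
            "protein-n-terminus",
            "peptide is protein-N-terminal and lacks an internal lysine",
        )
    if nterm_admissible and lysine_candidates:
        return SiteAssignment(
            "ambiguous",
            "both the protein N-terminus and an internal lysine are admissible",
        )
    return SiteAssignment(
        "inconsistent",
        "no admissible site: peptide is not protein-N-terminal and has no internal lysine",
    )
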