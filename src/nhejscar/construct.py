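"""Reporter-construct geometry for a two-cut GFP end-joining assay.

The assay construct is a GFP gene split by a large intron that carries a
"killer" exon flanked by two inverted I-SceI sites.  Double digestion excises
the killer exon; end joining of the two remaining intron ends restores GFP.
This module represents the annotated construct, derives the post-cut reference
flanks against which repair junctions are interpreted, and computes the
primer-bounded deletion detection window of the rescue PCR.

Coordinates are 1-based, closed intervals on the top strand throughout the
public API.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Union

import yaml
from Bio import SeqIO

_DNA_OK = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


class ConstructError(ValueError):
    """Base class for reporter-construct validation failures."""


class FastaRecordError(ConstructError):
    """The construct FASTA does not contain exactly one record."""


class CutSiteError(ConstructError):
    """A cut site is malformed, out of range, or the sites are unordered."""


class ExcisedIntervalError(ConstructError):
    """The excised interval is inverted or not strictly inside the sequence."""


class PrimerError(ConstructError):
    """A rescue primer is absent, non-unique, or not rescuable."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_alphabet(seq: str, what: str, allow_n: bool = True) -> None:
    allowed = _DNA_OK if allow_n else frozenset("ACGT")
    bad = set(seq) - allowed
    if bad:
        raise ConstructError(f"{what} contains non-DNA characters: {sorted(bad)}")


@dataclass(frozen=True)
class CutSite:
    """One endonuclease scission point on the construct.

    ``position`` is the 1-based index of the top-strand scission point.
    I-SceI leaves 4-nt 3' overhangs; whether overhang bases end up on a flank
    is decided by the annotation's excised interval (see module docs), so
    ``overhang_length`` is descriptive metadata, not a structural model.
    """

    position: int
    overhang_length: int = 4
    orientation: str = "forward"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise CutSiteError(f"cut position must be >= 1, got {self.position}")
        if self.overhang_length < 0:
            raise CutSiteError("overhang_length must be >= 0")
        if self.orientation not in ("forward", "reverse"):
            raise CutSiteError(
                f"orientation must be 'forward' or 'reverse', got {self.orientation!r}"
            )


@dataclass(frozen=True)
class ReporterConstruct:
    """The annotated reporter sequence.

    ``excised_interval`` is the 1-based closed interval removed by double
    digestion (killer exon plus inter-site DNA, including any overhang bases
    the annotation assigns to the excised piece rather than to a flank).
    """

    name: str
    sequence: str
    cut_sites: tuple[CutSite, CutSite]
    excised_interval: tuple[int, int]
    primer_fwd: str
    primer_rev: str

    def __post_init__(self) -> None:
        seq = self.sequence
        if not seq:
            raise ConstructError("construct sequence is empty")
        _check_alphabet(seq, "construct sequence")
        if len(self.cut_sites) != 2:
            raise CutSiteError(
                f"this assay requires exactly 2 cut sites, got {len(self.cut_sites)}"
            )
        c1, c2 = self.cut_sites
        if not (1 <= c1.position <= len(seq)) or not (1 <= c2.position <= len(seq)):
            raise CutSiteError("cut site position outside sequence")
        if c1.position >= c2.position:
            raise CutSiteError("cut sites must be strictly ordered and non-overlapping")
        s, e = self.excised_interval
        if s > e:
            raise ExcisedIntervalError(f"excised interval inverted: [{s}, {e}]")
        if not (1 < s and e < len(seq)):
            raise ExcisedIntervalError(
                f"excised interval [{s}, {e}] must lie strictly inside the "
                f"sequence (length {len(seq)})"
            )
        for primer, label in ((self.primer_fwd, "primer_fwd"), (self.primer_rev, "primer_rev")):
            if not primer:
                raise PrimerError(f"{label} is empty")
            _check_alphabet(primer, label, allow_n=False)
        self._locate_primer(self.primer_fwd, "primer_fwd")
        self._locate_primer(reverse_complement(self.primer_rev), "primer_rev")

    def _locate_primer(self, site: str, label: str) -> tuple[int, int]:
        """Find the unique occurrence of ``site``; return 1-based [start, end].

        The site must fall entirely outside the excised interval.
        """
        first = self.sequence.find(site)
        if first < 0:
            raise PrimerError(f"{label} not found in construct sequence")
        if self.sequence.find(site, first + 1) >= 0:
            raise PrimerError(f"{label} occurs more than once in construct sequence")
        start, end = first + 1, first + len(site)
        s, e = self.excised_interval
        if not (end < s or start > e):
            raise PrimerError(
                f"{label} annealing site [{start}, {end}] overlaps the excised "
                f"interval [{s}, {e}]; junctions would not be rescuable"
            )
        return start, end

    @property
    def excised_sequence(self) -> str:
        s, e = self.excised_interval
        return self.sequence[s - 1 : e]


@dataclass(frozen=True)
class CutReference:
    """Post-double-cut reference: the two retained intron flanks.

    The precise-excision (perfect rejoin) product is
    ``left_flank + right_flank``; ``cut_coordinate`` is the length of
    ``left_flank``, i.e. the last retained position of the left flank in
    joined coordinates.
    """

    left_flank: str
    right_flank: str
    cut_coordinate: int

    def __post_init__(self) -> None:
        if not self.left_flank or not self.right_flank:
            raise ConstructError("both flanks must be non-empty")
        if self.cut_coordinate != len(self.left_flank):
            raise ConstructError("cut_coordinate must equal len(left_flank)")

    @property
    def joined(self) -> str:
        return self.left_flank + self.right_flank


@dataclass(frozen=True)
class DetectionWindow:
    """Maximal deletion extents (bp) on each side of the break such that the
    rescue primers still anneal."""

    max_del_5prime: int
    max_del_3prime: int

    def __post_init__(self) -> None:
        if self.max_del_5prime < 0 or self.max_del_3prime < 0:
            raise ConstructError("detection window extents must be >= 0")


def load_construct(
    fasta_path: Union[str, Path],
    annotation: Union[str, Path, Mapping],
) -> ReporterConstruct:
    """Load and validate a reporter construct from FASTA plus annotation.

    Parameters
    ----------
    fasta_path
        FASTA file containing exactly one record (the full construct).
    annotation
        Mapping, or path to a YAML file, with keys ``cut_sites`` (list of
        ``{position, overhang_length, orientation}``), ``excised_interval``
        (``[start, end]``, 1-based closed), ``primer_fwd`` and ``primer_rev``
        (primer sequences as printed, 5'->3'; the reverse primer is located as
        its reverse complement on the top strand).
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if len(records) != 1:
        raise FastaRecordError(
            f"expected exactly one FASTA record in {fasta_path}, found {len(records)}"
        )
    record = records[0]
    if not isinstance(annotation, Mapping):
        with open(annotation) as fh:
            annotation = yaml.safe_load(fh)
    try:
        cut_sites = tuple(
            CutSite(
                position=int(cs["position"]),
                overhang_length=int(cs.get("overhang_length", 4)),
                orientation=str(cs.get("orientation", "forward")),
            )
            for cs in annotation["cut_sites"]
        )
        excised = tuple(int(x) for x in annotation["excised_interval"])
        primer_fwd = str(annotation["primer_fwd"]).upper()
        primer_rev = str(annotation["primer_rev"]).upper()
    except KeyError as exc:
        raise ConstructError(f"annotation is missing required key: {exc}") from exc
    return ReporterConstruct(
        name=str(annotation.get("name", record.id)),
        sequence=str(record.seq).upper(),
        cut_sites=cut_sites,  # type: ignore[arg-type]
        excised_interval=excised,  # type: ignore[arg-type]
        primer_fwd=primer_fwd,
        primer_rev=primer_rev,
    )


def derive_cut_reference(construct: ReporterConstruct) -> CutReference:
    """Derive the post-cut flanks by removing the excised interval.

    ``left_flank`` is everything 5' of the excised interval, ``right_flank``
    everything 3' of it; any retained overhang bases are simply part of the
    flank strings as placed by the annotation.  Slicing-exact:
    ``left_flank + excised_sequence + right_flank == sequence``.
    """
    s, e = construct.excised_interval
    left = construct.sequence[: s - 1]
    right = construct.sequence[e:]
    return CutReference(left_flank=left, right_flank=right, cut_coordinate=len(left))


def detection_window(
    construct: ReporterConstruct, cutref: CutReference
) -> DetectionWindow:
    """Compute the primer-bounded deletion detection window.

    ``max_del_5prime`` is the number of bases between the 3' end of the
    forward-primer annealing site and the left cut edge; ``max_del_3prime``
    analogously between the right cut edge and the 5'-most base (top strand)
    of the reverse-primer annealing site.
    """
    fwd = construct.primer_fwd
    pos_f = cutref.left_flank.find(fwd)
    if pos_f < 0 or cutref.left_flank.find(fwd, pos_f + 1) >= 0:
        raise PrimerError(
            "forward primer must anneal exactly once on the left flank"
        )
    max5 = len(cutref.left_flank) - (pos_f + len(fwd))

    rc_rev = reverse_complement(construct.primer_rev)
    pos_r = cutref.right_flank.find(rc_rev)
    if pos_r < 0 or cutref.right_flank.find(rc_rev, pos_r + 1) >= 0:
        raise PrimerError(
            "reverse primer must anneal exactly once on the right flank"
        )
    max3 = pos_r
    return DetectionWindow(max_del_5prime=max5, max_del_3prime=max3)
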