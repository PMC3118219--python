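"""Gene neighborhoods and endolysin-holin architecture calls.

In most phages the holin gene sits immediately upstream of the endolysin in
the direction of transcription; the reversed arrangement (holin immediately
downstream of the endolysin) is the rarer architecture of interest here.
Upstream/downstream are defined relative to the focal gene's strand: for a
minus-strand focal gene, downstream means decreasing genome coordinates.
Adjacency ignores intergenic distance by default (an optional ``max_gap``
imposes a bp cutoff) and neighbors on the opposite strand still count but
are flagged strand-discordant.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

from .errors import FormatError, TreeError
from .seqio import FeatureRecord, GenomeAnnotation

ENDOLYSIN_FAMILIES = {"PF01520", "COG0860"}
HOLIN_FAMILIES = {"PF04531"}
ENDOLYSIN_PRODUCT_RE = re.compile(r"endolysin|amidase", re.IGNORECASE)
HOLIN_PRODUCT_RE = re.compile(r"holin", re.IGNORECASE)

HOLIN_UPSTREAM = "holin_upstream"      # the typical architecture
HOLIN_DOWNSTREAM = "holin_downstream"  # the reversed arrangement
NOT_ADJACENT = "not_adjacent"


@dataclass
class ArchitectureCall:
    genome_id: str
    focal_gene_id: str
    upstream: str | None
    downstream: str | None
    label: str
    strand_discordant: list[str] | None = None


def is_endolysin(feature: FeatureRecord) -> bool:
    return bool(
        set(feature.family_labels) & ENDOLYSIN_FAMILIES
        or ENDOLYSIN_PRODUCT_RE.search(feature.product)
    )


def is_holin(feature: FeatureRecord) -> bool:
    return bool(
        set(feature.family_labels) & HOLIN_FAMILIES
        or HOLIN_PRODUCT_RE.search(feature.product)
    )


def extract_neighborhood(
    annotation: GenomeAnnotation, focal_id: str, k: int = 1
) -> tuple[list[FeatureRecord], list[FeatureRecord]]:
    """The k genes upstream and downstream of the focal gene.

    Returned in transcription order relative to the focal strand: the last
    element of the upstream list is the immediate upstream neighbor, the
    first element of the downstream list the immediate downstream one.
    """
    features = annotation.features
    index = next(
        (i for i, f in enumerate(features) if f.gene_id == focal_id), None
    )
    if index is None:
        raise FormatError(
            f"focal gene {focal_id!r} absent from genome {annotation.genome_id!r}"
        )
    before = features[max(0, index - k) : index]
    after = features[index + 1 : index + 1 + k]
    if features[index].strand == "+":
        return before, after
    # minus strand: transcription runs toward decreasing coordinates
    return after[::-1], before[::-1]


def classify_lysis_architecture(
    annotation: GenomeAnnotation,
    focal_id: str | None = None,
    max_gap: int | None = None,
) -> ArchitectureCall:
    """Classify the endolysin-holin arrangement of one genome.

    The focal gene is the endolysin (located by family label or product
    regex when ``focal_id`` is not given).  The call is ``holin_downstream``
    when the immediate transcription-downstream neighbor is a holin,
    ``holin_upstream`` when the immediate upstream neighbor is, otherwise
    ``not_adjacent``.  A holin on both sides is ambiguous and raises.
    """
    if focal_id is None:
        endolysins = [f for f in annotation.features if is_endolysin(f)]
        if not endolysins:
            raise FormatError(
                f"no endolysin found in genome {annotation.genome_id!r}"
            )
        if len(endolysins) > 1:
            raise FormatError(
                f"multiple endolysins in genome {annotation.genome_id!r}: "
                f"{[f.gene_id for f in endolysins]}"
            )
        focal = endolysins[0]
    else:
        focal = annotation.feature(focal_id)
    upstream_genes, downstream_genes = extract_neighborhood(
        annotation, focal.gene_id, k=1
    )
    upstream = upstream_genes[-1] if upstream_genes else None
    downstream = downstream_genes[0] if downstream_genes else None

    def _gap(a: FeatureRecord, b: FeatureRecord) -> int:
        return max(a.start, b.start) - min(a.end, b.end) - 1

    def _qualifies(neighbor: FeatureRecord | None) -> bool:
        if neighbor is None or not is_holin(neighbor):
            return False
        if max_gap is not None and _gap(focal, neighbor) > max_gap:
            return False
        return True

    up_holin = _qualifies(upstream)
    down_holin = _qualifies(downstream)
    if up_holin and down_holin:
        raise FormatError(
            f"ambiguous architecture in {annotation.genome_id!r}: holins on both "
            f"sides of {focal.gene_id!r} ({upstream.gene_id!r}, {downstream.gene_id!r})"
        )
    if down_holin:
        label = HOLIN_DOWNSTREAM
    elif up_holin:
        label = HOLIN_UPSTREAM
    else:
        label = NOT_ADJACENT
    discordant = [
        n.gene_id
        for n in (upstream, downstream)
        if n is not None and n.strand != focal.strand
    ]
    return ArchitectureCall(
        genome_id=annotation.genome_id,
        focal_gene_id=focal.gene_id,
        upstream=upstream.gene_id if upstream else None,
        downstream=downstream.gene_id if downstream else None,
        label=label,
        strand_discordant=discordant or None,
    )


def write_architecture_calls(
    calls: Sequence[ArchitectureCall], path
) -> None:
    """Tabular record of calls: genome, focal, upstream, downstream, label."""
    with open(path, "w") as fh:
        fh.write("genome_id\tfocal_gene\tupstream\tdownstream\tlabel\n")
        for c in calls:
            fh.write(
                f"{c.genome_id}\t{c.focal_gene_id}\t{c.upstream or '.'}\t"
                f"{c.downstream or '.'}\t{c.label}\n"
            )
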