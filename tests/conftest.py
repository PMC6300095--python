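import pytest

from hgtscreen.taxonomy import LineageTable


@pytest.fixture
def toy_lineages() -> LineageTable:
    """Small lineage table: 3 bacteria, 3 plants, 1 fungus, 1 archaeon."""
    t = LineageTable()
    for i in range(1, 4):
        t.add(
            f"b{i}",
            [("superkingdom", "Bacteria"), ("genus", "Streptomyces")],
        )
    for i in range(1, 4):
        t.add(
            f"p{i}",
            [
                ("superkingdom", "Eukaryota"),
                ("kingdom", "Viridiplantae"),
                ("genus", "Arabidopsis"),
            ],
        )
    t.add("f1", [("superkingdom", "Eukaryota"), ("kingdom", "Fungi")])
    t.add("a1", [("superkingdom", "Archaea")])
    return t


def make_hit(query="q1", subject="s1", taxon="b1", bitscore=100.0, **kw):
    from hgtscreen.hit_screen import HomologyHit

    defaults = dict(
        query_id=query,
        subject_id=subject,
        taxon_id=taxon,
        percent_identity=50.0,
        alignment_length=100,
        evalue=1e-10,
        bitscore=bitscore,
    )
    defaults.update(kw)
    return HomologyHit(**defaults)


@pytest.fixture
def hit_factory():
    return make_hit
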