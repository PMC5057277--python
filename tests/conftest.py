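import pytest

from fmapy.refdb import OperonSet, PathwaySet, ProteinRecord, ReferenceDB


def make_db(proteins, pathways=(), operons=()):
    """proteins: iterable of (protein_id, ko_id, length_aa)."""
    return ReferenceDB(
        proteins={
            pid: ProteinRecord(protein_id=pid, ko_id=ko, length_aa=length)
            for pid, ko, length in proteins
        },
        pathways=[
            PathwaySet(pathway_id=pid, name=name, members=frozenset(members))
            for pid, name, members in pathways
        ],
        operons=[
            OperonSet(operon_id=oid, members=tuple(members), label=label)
            for oid, members, label in operons
        ],
    )


def m8_line(read_id, protein_id, identity=95.0, evalue=1e-10, bitscore=200.0,
            align_length=40, mismatches=2):
    fields = [read_id, protein_id, f"{identity:.1f}", str(align_length),
              str(mismatches), "0", "1", str(align_length * 3), "10",
              str(10 + align_length - 1), f"{evalue:.3e}", f"{bitscore:.1f}"]
    return "\t".join(fields)


@pytest.fixture
def small_db():
    return make_db(
        proteins=[
            ("P1", "K00001", 300),
            ("P2", "K00002", 100),
            ("P3", "K00003", 250),
            ("P4", "K00003", 180),
        ],
        pathways=[("map00010", "glycolysis", ["K00001", "K00002"])],
        operons=[("OP1", ["K00001", "K00002"], "test operon")],
    )
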