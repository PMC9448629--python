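import pytest

from tcmrules.records import Item, MedicalRecord, Role


def sym(*tokens):
    return frozenset(Item(t, Role.SYMPTOM) for t in tokens)


def make_record(record_id, symptoms, constitution, regimen=(), **kwargs):
    return MedicalRecord(
        record_id=record_id,
        symptoms=sym(*symptoms),
        primary_constitution=Item(constitution, Role.CONSTITUTION),
        regimen=frozenset(Item(t, Role.REGIMEN) for t in regimen),
        **kwargs,
    )


@pytest.fixture
def toy_transactions():
    """{A,B}, {B,C}, {A,B,C}: the worked FP-growth example database."""
    return [sym("a", "b"), sym("b", "c"), sym("a", "b", "c")]


@pytest.fixture
def three_records():
    return [
        make_record("r1", ["fatigue", "pale face"], "QDC", ["tonify qi"]),
        make_record("r2", ["red tongue", "dry mouth"], "YIDC", ["nourish yin"]),
        make_record("r3", ["energetic"], "BC", ["balanced diet"],
                    diseases=frozenset({Item("hypertension", Role.DISEASE)}),
                    drugs=frozenset({Item("licorice root", Role.DRUG)})),
    ]
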