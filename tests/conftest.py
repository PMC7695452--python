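import pytest

from fsclineage.model import Observation, ScoringTable


def make_obs(
    gid="g1",
    genotype="control",
    day=6.0,
    l1=1,
    l2=1,
    l3=0,
    edu=(0, 0, 0),
    ec=0,
    edu_ec=0,
    immediate=False,
    any_fc=False,
):
    return Observation(
        germarium_id=gid,
        genotype=genotype,
        day=day,
        n_marked_l1=l1,
        n_marked_l2=l2,
        n_marked_l3=l3,
        edu_l1=edu[0],
        edu_l2=edu[1],
        edu_l3=edu[2],
        n_marked_ec=ec,
        edu_ec=edu_ec,
        immediate_fc_present=immediate,
        any_fc_present=any_fc,
    )


@pytest.fixture
def small_table():
    """Four scored germaria spanning the informative grouping cases."""
    return ScoringTable(
        observations=[
            make_obs("g1", l1=1, immediate=True, any_fc=True),
            make_obs("g2", l1=1, immediate=False),
            make_obs("g3", l1=2, l2=0, edu=(1, 0, 0), immediate=True, any_fc=True),
            make_obs("g4", l1=0, l2=2, l3=1, ec=2, immediate=False),
        ],
        metadata={"experiment": "unit-test"},
    )
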