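import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from snpmeta.genetic_models import FourfoldTable, study_effect
from snpmeta.study_corpus import GenotypeCounts, StudyCorpus, StudyRecord


def make_study(study_id="s1", ethnicity="Asian", country="China",
               cases=(10, 20, 30), controls=(5, 15, 40), allele_only=False,
               year=2012):
    def arm(triple):
        g = GenotypeCounts(n_TT=triple[0], n_TC=triple[1], n_CC=triple[2])
        if allele_only:
            t, c = g.allele_counts()
            return GenotypeCounts(n_T=t, n_C=c)
        return g
    return StudyRecord(
        study_id=study_id, first_author=study_id, year=year, country=country,
        ethnicity=ethnicity,
        resolution="allele_only" if allele_only else "genotype",
        cases=arm(cases), controls=arm(controls), platform="test",
    )


@pytest.fixture
def toy_study():
    return make_study()


@pytest.fixture
def toy_tables():
    """Five allele-model 2x2 tables cross-checked against an independent
    reference implementation (values frozen in test_meta_engine)."""
    cells = [(40, 80, 25, 95), (20, 80, 10, 90), (15, 85, 20, 80),
             (30, 70, 30, 70), (12, 58, 19, 51)]
    return [FourfoldTable(a, b, c, d, model="allele", study_id=f"s{i}")
            for i, (a, b, c, d) in enumerate(cells)]


@pytest.fixture
def toy_effects(toy_tables):
    return [study_effect(t) for t in toy_tables]


@pytest.fixture
def small_corpus():
    """Six-study corpus spanning the subgroup structure."""
    studies = [
        make_study("a_China", "Asian", "China", (50, 180, 170), (60, 190, 150)),
        make_study("b_China", "Asian", "China", (40, 160, 200), (55, 170, 175)),
        make_study("c_Korea", "Asian", "Korea", (30, 140, 230), (45, 160, 195)),
        make_study("d_India", "Asian", "India", (35, 150, 215), (50, 165, 185)),
        make_study("e_USA", "Caucasian", "USA", (60, 190, 150), (80, 200, 120)),
        make_study("f_UK", "Caucasian", "UK", (55, 185, 160), (75, 195, 130),
                   allele_only=True),
    ]
    return StudyCorpus(studies, source="<fixture>")
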