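"""LIPOR complement classification, summaries, and the exact association test."""

import io
import itertools
from math import comb

import numpy as np
import pytest

from portrace.lipor import (
    GENE_STATUSES,
    COMPLEMENT_CLASSES,
    LiporRecord,
    classify_complement,
    load_reference_complements,
    parse_complement_table,
    por_lipor_association,
    summarize_by_group,
)
from portrace.records import InputError


def rec(chlL, chlN, chlB, por=None, species="sp", group="g"):
    return LiporRecord(species, group, chlL, chlN, chlB, por_count=por)


def fisher_two_sided_oracle(table) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    return sum(
        prob(k) for k in range(0, c1 + 1) if prob(k) <= p_obs * (1 + 1e-9)
    )


class TestClassifyComplement:
    @pytest.mark.parametrize(
        "statuses,expected",
        [
            (("present", "present", "present"), "complete"),
            (("present", "present", "absent"), "partial"),
            (("pseudogene", "pseudogene", "pseudogene"), "pseudogenized"),
            (("absent", "absent", "absent"), "absent"),
            (("present", "pseudogene", "unknown"), "indeterminate"),
            (("present_multi", "present_multi", "present"), "complete"),
            (("present", "unknown", "present"), "indeterminate"),
            (("pseudogene", "absent", "absent"), "pseudogenized"),
        ],
    )
    def test_known_combinations(self, statuses, expected):
        assert classify_complement(rec(*statuses)) == expected

    def test_total_over_all_status_combinations(self):
        for combo in itertools.product(GENE_STATUSES, repeat=3):
            cls = classify_complement(rec(*combo))
            assert cls in COMPLEMENT_CLASSES


class TestSummaries:
    def test_row_sums_equal_group_sizes(self):
        records = [
            rec("present", "present", "present", group="a"),
            rec("absent", "absent", "absent", group="a"),
            rec("present", "present", "absent", group="b"),
        ]
        table = summarize_by_group(records)
        counts = table.set_index("group")
        for group in ("a", "b"):
            row = counts.loc[group]
            total = (
                row.n_complete + row.n_partial + row.n_pseudogenized
                + row.n_absent + row.n_indeterminate
            )
            assert total == row.n_species

    def test_concatenation_adds_summaries(self):
        first = [rec("present", "present", "present", group="a")]
        second = [rec("absent", "absent", "absent", group="a")]
        combined = summarize_by_group(first + second).set_index("group")
        assert combined.loc["a", "n_species"] == 2
        assert combined.loc["a", "n_complete"] == 1
        assert combined.loc["a", "n_absent"] == 1


class TestAssociation:
    def test_pelagophycean_pattern(self):
        records = [
            rec("absent", "absent", "absent", por=2, species="Aureococcus"),
            rec("absent", "absent", "absent", por=2, species="Pelagomonas"),
            rec("present", "present", "present", por=1, species="Aureoumbra"),
        ]
        result = por_lipor_association(records)
        assert result.table.tolist() == [[2, 0], [0, 1]]
        assert 0 < result.p_value <= 1

    def test_degenerate_table_has_p_one(self):
        records = [
            rec("present", "present", "present", por=1, species=f"s{i}")
            for i in range(5)
        ]
        result = por_lipor_association(records)
        assert result.p_value == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 8, size=4)
            if a + b + c + d == 0:
                continue
            records = (
                [rec("absent", "absent", "absent", por=2, species=f"a{i}")
                 for i in range(a)]
                + [rec("present", "present", "present", por=2, species=f"b{i}")
                   for i in range(b)]
                + [rec("absent", "absent", "absent", por=1, species=f"c{i}")
                   for i in range(c)]
                + [rec("present", "present", "present", por=1, species=f"d{i}")
                   for i in range(d)]
            )
            result = por_lipor_association(records)
            expected = fisher_two_sided_oracle([[a, b], [c, d]])
            assert result.p_value == pytest.approx(expected, rel=1e-9)

    def test_indeterminate_and_unknown_por_excluded(self):
        records = [
            rec("absent", "absent", "absent", por=2),
            rec("present", "unknown", "present", por=2),
            rec("present", "present", "present", por=None),
        ]
        result = por_lipor_association(records)
        assert result.n_included == 1
        assert result.n_excluded == 2

    def test_no_usable_records_is_an_error(self):
        with pytest.raises(InputError):
            por_lipor_association([rec("present", "unknown", "present", por=1)])


class TestParsing:
    def test_symbols_mapped(self):
        text = (
            "species\tgroup\tchlL\tchlN\tchlB\tpor_count\n"
            "Vitrella brassicaformis\tChromerida\t+,2\t+, 2\t+\t1\n"
            "Mystery sp.\tChromerida\t?\t-\tψ\t1-2\n"
        )
        records = parse_complement_table(io.StringIO(text))
        assert records[0].chlL == "present_multi"
        assert records[0].chlN == "present_multi"
        assert records[0].chlB == "present"
        assert records[1].chlL == "unknown"
        assert records[1].chlN == "absent"
        assert records[1].chlB == "pseudogene"
        assert records[1].por_count == 1
        assert records[1].por_count_max == 2

    def test_unknown_symbol_reports_row(self):
        text = (
            "species\tgroup\tchlL\tchlN\tchlB\n"
            "Bad sp.\tg\t+\t%\t-\n"
        )
        with pytest.raises(InputError, match="row 2"):
            parse_complement_table(io.StringIO(text))

    def test_empty_file_gives_empty_list(self):
        assert parse_complement_table(io.StringIO("")) == []


class TestReferenceTables:
    def test_reference_survey_loads(self):
        records = load_reference_complements()
        assert len(records) == 85
        by_species = {r.species: r for r in records}
        assert by_species["Vitrella brassicaformis"].chlL == "present_multi"
        assert by_species["Rhodomonas salina"].por_count == 1
        assert by_species["Rhodomonas salina"].por_count_max == 2

    def test_euglenid_rows_all_absent(self):
        records = [
            r for r in load_reference_complements() if r.group == "Euglenozoa"
        ]
        table = summarize_by_group(records)
        assert int(table.n_species.iloc[0]) == 4
        assert int(table.n_absent.iloc[0]) == 4
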