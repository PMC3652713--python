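import random
import re

import pytest
from hypothesis import given, settings, strategies as st

from mcckit.code_systems import CodeSystem, ContractError, ValidationError
from mcckit.coder import (
    ClaimRecord,
    CodingConfig,
    ConditionProfile,
    SurveyRecord,
    claims_from_csv,
    code_claims_unit,
    code_population,
    code_survey_unit,
    profiles_from_csv,
    profiles_to_csv,
    profiles_to_jsonl,
    records_from_jsonl,
    surveys_from_csv,
)
from mcckit.registry import Availability


def claim(unit, rec, codes, system=CodeSystem.ICD9CM):
    return ClaimRecord(unit_id=unit, record_id=rec, codes=tuple(codes),
                       code_system=system)


# ---------------------------------------------------------------------------
# Independent oracle: a brute-force scan of claim codes against the raw
# printed mapping cells, reimplemented here without any package parsing.


def brute_force_condition_codes(raw_resource, dialect_id):
    out = {}
    for raw_cond in raw_resource["conditions"]:
        members = set()
        for row in raw_cond["rows"]:
            cell = row["cells"][dialect_id]["cell"]
            low = cell.lower()
            if low.startswith(("not applicable", "included in", "self-report",
                               "checkbox")) or low in ("—", "-"):
                continue
            text = re.sub(r"[A-Za-z][A-Za-z ]*:\s*", "", cell)
            for tok in re.split(r"[,\s]+", text):
                tok = tok.strip().rstrip(".")
                if not tok:
                    continue
                m = re.fullmatch(r"(\d+)[–-](\d+)", tok)
                if m:
                    members.update(
                        str(v) for v in range(int(m.group(1)), int(m.group(2)) + 1)
                    )
                elif re.fullmatch(r"V?\d+(\.\d+)?", tok):
                    compact = tok.replace(".", "")
                    if dialect_id == "CMS":
                        if len(compact.lstrip("V")) >= 3:
                            members.add(compact)
                    else:
                        members.add(str(int(compact)))
        out[raw_cond["condition_id"]] = members
    return out


def brute_force_profile(unit_codes, condition_codes):
    return {
        cid: any(c in members for c in unit_codes)
        for cid, members in condition_codes.items()
    }


class TestCodeClaimsUnit:
    def test_overlapping_code_sets_two_flags(self, registry):
        profile = code_claims_unit(
            [claim("p1", "r1", ["40201"])], "CMS", registry=registry
        )
        assert profile.flags["hypertension"]
        assert profile.flags["congestive_heart_failure"]
        assert profile.n_conditions == 2

    def test_two_conditions(self, registry):
        profile = code_claims_unit(
            [claim("p1", "r1", ["4019", "25000"])], "CMS", registry=registry
        )
        assert profile.flags["hypertension"]
        assert profile.flags["diabetes"]
        assert profile.n_conditions == 2

    def test_no_matches(self, registry):
        profile = code_claims_unit(
            [claim("p1", "r1", ["79999"])], "CMS", registry=registry
        )
        assert profile.n_conditions == 0
        assert not any(profile.flags.values())

    def test_min_records_threshold(self, registry):
        config = CodingConfig(min_records_per_condition=2)
        one = code_claims_unit(
            [claim("p1", "r1", ["4280"])], "CMS", config, registry=registry
        )
        assert not one.flags["congestive_heart_failure"]
        two = code_claims_unit(
            [claim("p1", "r1", ["4280"]), claim("p1", "r2", ["4281"])],
            "CMS", config, registry=registry,
        )
        assert two.flags["congestive_heart_failure"]

    def test_same_record_counts_once(self, registry):
        config = CodingConfig(min_records_per_condition=2)
        profile = code_claims_unit(
            [claim("p1", "r1", ["4280", "4281"])], "CMS", config,
            registry=registry,
        )
        assert not profile.flags["congestive_heart_failure"]

    def test_mixed_units_rejected(self, registry):
        with pytest.raises(ContractError):
            code_claims_unit(
                [claim("p1", "r1", ["4280"]), claim("p2", "r2", ["4280"])],
                "CMS", registry=registry,
            )

    def test_survey_dialect_rejected(self, registry):
        with pytest.raises(ContractError):
            code_claims_unit([claim("p1", "r1", ["4280"])], "NHIS",
                             registry=registry)

    def test_unknown_code_policies(self, registry):
        bad = [claim("p1", "r1", ["not-a-code", "4280"])]
        with pytest.raises(ValidationError):
            code_claims_unit(bad, "CMS",
                             CodingConfig(unknown_code_policy="error"),
                             registry=registry)
        profile = code_claims_unit(
            bad, "CMS", CodingConfig(unknown_code_policy="ignore"),
            registry=registry,
        )
        assert profile.flags["congestive_heart_failure"]

    def test_evidence_lists_matching_codes(self, registry):
        profile = code_claims_unit(
            [claim("p1", "r1", ["4019", "25000"])], "CMS", registry=registry
        )
        assert profile.evidence["hypertension"] == ("4019",)
        assert profile.evidence["diabetes"] == ("25000",)

    def test_prefix_matching_mode(self, registry):
        # 585.1 is a listed CKD code and a prefix of 585.12.
        config = CodingConfig(prefix_matching=True)
        profile = code_claims_unit(
            [claim("p1", "r1", ["58512"])], "CMS", config, registry=registry
        )
        assert profile.flags["chronic_kidney_disease"]
        exact = code_claims_unit(
            [claim("p1", "r1", ["58512"])], "CMS", registry=registry
        )
        assert not exact.flags["chronic_kidney_disease"]

    def test_ccs_dialect(self, registry):
        profile = code_claims_unit(
            [claim("h1", "r1", ["108"], CodeSystem.CCS)], "NIS",
            registry=registry,
        )
        assert profile.flags["congestive_heart_failure"]
        assert profile.flags["chronic_kidney_disease"]


class TestCodeSurveyUnit:
    def test_direct_items(self, registry):
        record = SurveyRecord("p1", {"hypertension": "yes", "asthma": "no"})
        profile = code_survey_unit(record, "NHIS", registry=registry)
        assert profile.flags["hypertension"]
        assert not profile.flags["asthma"]
        assert profile.n_conditions == 1

    def test_unavailable_condition_stays_false(self, registry, caplog):
        record = SurveyRecord("p1", {"depression": "yes"})
        with caplog.at_level("WARNING"):
            profile = code_survey_unit(record, "NHIS", registry=registry)
        assert not profile.flags["depression"]
        assert any("depression" in m for m in caplog.messages)

    def test_all_missing(self, registry):
        items = {cid: "missing" for cid in registry.survey_items("NHIS")}
        profile = code_survey_unit(SurveyRecord("p1", items), "NHIS",
                                   registry=registry)
        assert profile.n_conditions == 0

    def test_kidney_proxy_label(self, registry):
        record = SurveyRecord("p1", {"weak or failing kidneys": "yes"})
        profile = code_survey_unit(record, "NHIS", registry=registry)
        assert profile.flags["chronic_kidney_disease"]

    def test_kidney_proxy_disabled(self, registry):
        record = SurveyRecord("p1", {"weak or failing kidneys": "yes"})
        profile = code_survey_unit(
            record, "NHIS", CodingConfig(kidney_proxy_as_ckd=False),
            registry=registry,
        )
        assert not profile.flags["chronic_kidney_disease"]

    def test_namcs_checkbox(self, registry):
        record = SurveyRecord("v1", {"schizophrenia": "yes"})
        profile = code_survey_unit(record, "NAMCS", registry=registry)
        assert profile.flags["schizophrenia"]

    def test_code_dialect_rejected(self, registry):
        with pytest.raises(ContractError):
            code_survey_unit(SurveyRecord("p1", {}), "CMS", registry=registry)

    def test_invalid_response_rejected(self):
        with pytest.raises(ValidationError):
            SurveyRecord("p1", {"asthma": "maybe"})


class TestCodePopulation:
    def test_three_units(self, registry):
        records = [
            claim("a", "r1", ["4280"]),
            claim("b", "r2", ["25000"]),
            claim("c", "r3", ["79999"]),
        ]
        profiles = code_population(records, "CMS", registry=registry)
        assert [p.unit_id for p in profiles] == ["a", "b", "c"]

    def test_duplicate_rows_idempotent(self, registry):
        records = [claim("a", "r1", ["4280"])]
        duplicated = records * 3
        p1 = code_population(records, "CMS", registry=registry)
        p2 = code_population(duplicated, "CMS", registry=registry)
        assert p1 == p2

    def test_permutation_invariance(self, registry):
        rng = random.Random(7)
        records = [
            claim(f"u{i % 10}", f"r{i}", [code])
            for i, code in enumerate(
                ["4280", "25000", "4019", "42731", "2720", "49300"] * 5
            )
        ]
        baseline = code_population(records, "CMS", registry=registry)
        for _ in range(100):
            shuffled = records[:]
            rng.shuffle(shuffled)
            assert code_population(shuffled, "CMS", registry=registry) == baseline

    def test_roster_adds_empty_profiles(self, registry):
        records = [claim("a", "r1", ["4280"])]
        profiles = code_population(
            records, "CMS", registry=registry, unit_ids=["a", "b", "c"]
        )
        assert [p.unit_id for p in profiles] == ["a", "b", "c"]
        assert profiles[1].n_conditions == 0

    def test_mixing_record_types_rejected(self, registry):
        with pytest.raises(ContractError):
            code_population(
                [claim("a", "r1", ["4280"]),
                 SurveyRecord("b", {"asthma": "yes"})],
                "CMS", registry=registry,
            )

    def test_oracle_equivalence(self, registry, raw_resource):
        # Brute-force scan against raw printed cells on a random population.
        rng = random.Random(2024)
        for dialect in ("CMS", "MEPS", "NIS"):
            condition_codes = brute_force_condition_codes(raw_resource, dialect)
            pool = sorted(set().union(*condition_codes.values()))
            decoys = ["79999", "88888"] if dialect == "CMS" else ["999", "998"]
            system = (CodeSystem.ICD9CM if dialect == "CMS" else CodeSystem.CCS)
            records, truth_codes = [], {}
            for u in range(50):
                uid = f"u{u:02d}"
                codes = rng.sample(pool, rng.randint(0, 4)) + (
                    [rng.choice(decoys)] if rng.random() < 0.3 else []
                )
                truth_codes[uid] = codes
                for j, c in enumerate(codes):
                    records.append(claim(uid, f"{uid}-r{j}", [c], system))
            profiles = code_population(
                records, dialect, registry=registry,
                unit_ids=list(truth_codes),
            )
            matrix = registry.availability()
            for p in profiles:
                expected = brute_force_profile(
                    truth_codes[p.unit_id], condition_codes
                )
                for cid, flag in p.flags.items():
                    if matrix.state(cid, dialect) is Availability.UNAVAILABLE:
                        assert not flag
                    else:
                        assert flag == expected[cid], (dialect, p.unit_id, cid)


# ---------------------------------------------------------------------------
# Properties

CMS_CODES = ["4280", "25000", "4019", "42731", "2720", "49300", "43301",
             "71400", "29620", "5853", "79999", "40201"]


@settings(max_examples=30, deadline=None)
@given(
    codes=st.lists(st.sampled_from(CMS_CODES), min_size=1, max_size=8),
    extra=st.sampled_from(CMS_CODES),
)
def test_monotonicity_adding_record(registry_module, codes, extra):
    registry = registry_module
    records = [claim("u", f"r{i}", [c]) for i, c in enumerate(codes)]
    before = code_claims_unit(records, "CMS", registry=registry)
    after = code_claims_unit(
        records + [claim("u", "rX", [extra])], "CMS", registry=registry
    )
    for cid, flag in before.flags.items():
        if flag:
            assert after.flags[cid]


@settings(max_examples=30, deadline=None)
@given(codes=st.lists(st.sampled_from(CMS_CODES), min_size=1, max_size=8))
def test_dialect_closure_unavailable_always_false(registry_module, codes):
    registry = registry_module
    records = [claim("u", f"r{i}", [c]) for i, c in enumerate(codes)]
    profile = code_claims_unit(records, "CMS", registry=registry)
    matrix = registry.availability()
    for cid, flag in profile.flags.items():
        if matrix.state(cid, "CMS") is Availability.UNAVAILABLE:
            assert not flag


@pytest.fixture(scope="module")
def registry_module():
    from mcckit.registry import load_default_registry

    return load_default_registry()


# ---------------------------------------------------------------------------
# File formats


class TestFileFormats:
    def test_claims_csv_round_trip(self, registry, tmp_path):
        path = tmp_path / "claims.csv"
        path.write_text(
            "unit_id,record_id,code,code_system\n"
            "a,r1,428.0,icd9cm\n"
            "a,r1,250.00,icd9cm\n"
            "b,r2,401.9,icd9cm\n"
        )
        records = claims_from_csv(path)
        assert len(records) == 2
        profiles = code_population(records, "CMS", registry=registry)
        assert profiles[0].n_conditions == 2

    def test_claims_csv_missing_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("unit_id,code\na,428.0\n")
        with pytest.raises(ValidationError, match="record_id"):
            claims_from_csv(path)

    def test_survey_csv(self, registry, tmp_path):
        path = tmp_path / "survey.csv"
        path.write_text(
            "unit_id,item,response\n"
            "a,hypertension,yes\n"
            "a,asthma,no\n"
            "b,diabetes,yes\n"
        )
        records = surveys_from_csv(path)
        profiles = code_population(records, "NHIS", registry=registry)
        assert profiles[0].flags["hypertension"]
        assert profiles[1].flags["diabetes"]

    def test_jsonl_records(self, registry, tmp_path):
        path = tmp_path / "records.jsonl"
        path.write_text(
            '{"unit_id": "a", "record_id": "r1", "codes": ["428.0"], '
            '"code_system": "icd9cm"}\n'
            '{"unit_id": "b", "record_id": "r2", "codes": ["401.9"], '
            '"code_system": "icd9cm"}\n'
        )
        records = records_from_jsonl(path)
        assert len(records) == 2

    def test_profiles_csv_round_trip(self, registry, tmp_path):
        profiles = code_population(
            [claim("a", "r1", ["4280"]), claim("b", "r2", ["25000"])],
            "CMS", registry=registry,
        )
        path = tmp_path / "profiles.csv"
        profiles_to_csv(profiles, path, metadata={"seed": 1})
        loaded = profiles_from_csv(path)
        assert [p.unit_id for p in loaded] == ["a", "b"]
        assert loaded[0].flags["congestive_heart_failure"]
        assert "# seed: 1" in path.read_text().splitlines()[0]

    def test_profiles_jsonl(self, registry, tmp_path):
        profiles = code_population(
            [claim("a", "r1", ["4280"])], "CMS", registry=registry
        )
        path = tmp_path / "profiles.jsonl"
        profiles_to_jsonl(profiles, path)
        import json

        obj = json.loads(path.read_text().splitlines()[0])
        assert obj["flags"]["congestive_heart_failure"] is True
        assert obj["evidence"]["congestive_heart_failure"] == ["4280"]
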