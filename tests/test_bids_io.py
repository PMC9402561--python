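"""Filename grammar, round trips, sidecar inheritance, JSON determinism."""

import json
import random

import numpy as np
import pytest

from qmribids import bids_io
from qmribids.bids_io import (
    CompositionError,
    LabelError,
    ParseError,
    ParsedName,
    build_filename,
    parse_filename,
    resolve_sidecar,
    save_nifti,
    load_volume,
    write_json,
)


class TestParseFilename:
    def test_mp2rage_member(self):
        p = parse_filename("sub-01_inv-1_part-mag_MP2RAGE.nii.gz")
        assert p.subject == "01"
        assert p.entities == {"inv": 1, "part": "mag"}
        assert p.suffix == "MP2RAGE"
        assert p.extension == ".nii.gz"

    def test_dam_member(self):
        p = parse_filename("sub-01_flip-2_TB1DAM.nii.gz")
        assert p.entities == {"flip": 2}
        assert p.suffix == "TB1DAM"

    def test_session_and_opaque_entities_are_preserved(self):
        p = parse_filename("sub-01_ses-pre_acq-highres_run-2_echo-1_MEGRE.nii")
        assert p.session == "pre"
        assert p.extras == {"acq": "highres", "run": "2"}
        assert p.entities == {"echo": 1}

    def test_invalid_part_label_raises_label_error(self):
        with pytest.raises(LabelError, match="part"):
            parse_filename("sub-01_part-real_MP2RAGE.nii.gz")

    @pytest.mark.parametrize(
        "bad",
        [
            "inv-1_MP2RAGE.nii.gz",        # no subject
            "sub-01_MP2RAGE",              # no extension
            "sub-01_echo-0_MEGRE.nii.gz",  # index < 1
            "sub-01_echo-x_MEGRE.nii.gz",  # non-integer index
            "sub-01_echo-1_echo-2_MEGRE.nii.gz",  # repeated entity
            "sub-01_echo-1.nii.gz",        # suffix token contains '-'
        ],
    )
    def test_malformed_names_rejected(self, bad):
        with pytest.raises(ParseError):
            parse_filename(bad)

    def test_parse_error_reports_character_position(self):
        with pytest.raises(ParseError, match="position 7"):
            parse_filename("sub-01_badtoken_stuff_MEGRE.nii.gz")


class TestBuildFilename:
    def test_indices_zero_padded(self):
        name = build_filename(
            ParsedName(subject="01", entities={"flip": 1}, suffix="VFA")
        )
        assert name == "sub-01_flip-01_VFA.nii.gz"

    def test_echo_padding(self):
        name = build_filename(
            ParsedName(subject="01", entities={"echo": 3}, suffix="MEGRE")
        )
        assert name == "sub-01_echo-03_MEGRE.nii.gz"

    def test_forbidden_entity_rejected(self):
        with pytest.raises(CompositionError, match="forbidden"):
            build_filename(
                ParsedName(subject="01", entities={"inv": 1}, suffix="MEGRE")
            )

    def test_entity_order_is_canonical(self):
        name = build_filename(
            ParsedName(
                subject="01",
                entities={"part": "mag", "inv": 2, "echo": 1},
                suffix="MP2RAGE",
            )
        )
        assert name == "sub-01_echo-01_inv-02_part-mag_MP2RAGE.nii.gz"


def _random_name(rng: random.Random) -> ParsedName:
    suffix, entity_pool = rng.choice(
        [
            ("MEGRE", ["echo", "part"]),
            ("VFA", ["flip", "part"]),
            ("MP2RAGE", ["inv", "part", "echo"]),
            ("MTS", ["flip", "mt", "part"]),
            ("MTR", ["mt"]),
        ]
    )
    entities = {}
    for key in entity_pool:
        if rng.random() < 0.7:
            if key == "mt":
                entities[key] = rng.choice(["on", "off"])
            elif key == "part":
                entities[key] = rng.choice(["mag", "phase"])
            else:
                entities[key] = rng.randint(1, 12)
    extras = {"acq": rng.choice(["a", "b"])} if rng.random() < 0.3 else {}
    return ParsedName(
        subject=f"{rng.randint(1, 99):02d}",
        session=rng.choice([None, "01", "pre"]),
        entities=entities,
        extras=extras,
        suffix=suffix,
        extension=rng.choice([".nii", ".nii.gz"]),
    )


def test_parse_build_round_trip_on_200_random_names():
    rng = random.Random(20220824)
    for _ in range(200):
        p = _random_name(rng)
        rebuilt = parse_filename(build_filename(p))
        assert rebuilt.subject == p.subject
        assert rebuilt.session == p.session
        assert rebuilt.entities == p.entities
        assert rebuilt.extras == p.extras
        assert rebuilt.suffix == p.suffix
        assert rebuilt.extension == p.extension
        # canonical names are a fixed point of parse.build
        assert build_filename(rebuilt) == build_filename(p)


try:
    from hypothesis import given, settings, strategies as st

    _index = st.integers(min_value=1, max_value=99)
    _label = st.sampled_from

    @st.composite
    def parsed_names(draw):
        suffix, pool = draw(
            st.sampled_from(
                [
                    ("MEGRE", {"echo": _index, "part": _label(["mag", "phase"])}),
                    ("VFA", {"flip": _index}),
                    ("MTS", {"flip": _index, "mt": _label(["on", "off"])}),
                    ("MP2RAGE", {"inv": _index, "part": _label(["mag", "phase"])}),
                ]
            )
        )
        entities = {
            k: draw(v) for k, v in pool.items() if draw(st.booleans())
        }
        return ParsedName(
            subject=draw(st.from_regex(r"[0-9]{2}", fullmatch=True)),
            session=draw(st.none() | st.from_regex(r"[a-z0-9]{1,4}", fullmatch=True)),
            entities=entities,
            extras=(
                {"acq": draw(st.from_regex(r"[a-z]{1,6}", fullmatch=True))}
                if draw(st.booleans())
                else {}
            ),
            suffix=suffix,
            extension=draw(st.sampled_from([".nii", ".nii.gz"])),
        )

    @given(parsed_names())
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_parse_build_identity_property(p):
        rebuilt = parse_filename(build_filename(p))
        assert rebuilt.entities == p.entities
        assert rebuilt.extras == p.extras
        assert (rebuilt.subject, rebuilt.session, rebuilt.suffix,
                rebuilt.extension) == (p.subject, p.session, p.suffix,
                                       p.extension)
        assert build_filename(rebuilt) == build_filename(p)

except ImportError:  # hypothesis is an optional test dependency
    pass


class TestSidecarInheritance:
    def _dataset(self, tmp_path):
        anat = tmp_path / "sub-01" / "anat"
        anat.mkdir(parents=True)
        for inv in (1, 2):
            for part in ("mag", "phase"):
                (anat / f"sub-01_inv-{inv}_part-{part}_MP2RAGE.nii.gz").write_bytes(
                    b""
                )
        return tmp_path, anat

    def test_single_json_shared_by_mag_and_phase(self, tmp_path):
        root, anat = self._dataset(tmp_path)
        write_json(anat / "sub-01_inv-1_MP2RAGE.json", {"InversionTime": 0.8})
        mag = resolve_sidecar(anat / "sub-01_inv-1_part-mag_MP2RAGE.nii.gz", root)
        phs = resolve_sidecar(anat / "sub-01_inv-1_part-phase_MP2RAGE.nii.gz", root)
        assert mag.values == phs.values == {"InversionTime": 0.8}
        other = resolve_sidecar(anat / "sub-01_inv-2_part-mag_MP2RAGE.nii.gz", root)
        assert "InversionTime" not in other

    def test_deeper_value_wins(self, tmp_path):
        root, anat = self._dataset(tmp_path)
        write_json(root / "MP2RAGE.json", {"FlipAngle": 4, "NumberShots": 160})
        write_json(anat / "sub-01_inv-1_MP2RAGE.json", {"FlipAngle": 5})
        side = resolve_sidecar(anat / "sub-01_inv-1_part-mag_MP2RAGE.nii.gz", root)
        assert side.get("FlipAngle") == 5
        assert side.get("NumberShots") == 160
        assert side.provenance[0].endswith("MP2RAGE.json")
        assert side.provenance[-1].endswith("sub-01_inv-1_MP2RAGE.json")

    def test_no_applicable_json_gives_empty_sidecar(self, tmp_path):
        root, anat = self._dataset(tmp_path)
        side = resolve_sidecar(anat / "sub-01_inv-1_part-mag_MP2RAGE.nii.gz", root)
        assert side.values == {} and side.provenance == []

    def test_invalid_json_raises_format_error_with_path(self, tmp_path):
        root, anat = self._dataset(tmp_path)
        (anat / "sub-01_inv-1_MP2RAGE.json").write_text("{not json", "utf-8")
        with pytest.raises(bids_io.FormatError, match="MP2RAGE.json"):
            resolve_sidecar(anat / "sub-01_inv-1_part-mag_MP2RAGE.nii.gz", root)

    def test_alias_keys_canonicalized(self, tmp_path):
        root, anat = self._dataset(tmp_path)
        write_json(root / "MP2RAGE.json", {"RFSpoilingPhaseIncrement": 50.0})
        side = resolve_sidecar(anat / "sub-01_inv-1_part-mag_MP2RAGE.nii.gz", root)
        assert side.get("SpoilingRFPhaseIncrement") == 50.0


def test_json_output_is_byte_stable(tmp_path):
    values = {"B": [1.0, 2.0], "A": 0.1234567890123456789, "C": "x"}
    write_json(tmp_path / "a.json", values)
    write_json(tmp_path / "b.json", dict(reversed(values.items())))
    a = (tmp_path / "a.json").read_bytes()
    assert a == (tmp_path / "b.json").read_bytes()
    assert json.loads(a)["A"] == 0.123456789012  # 12 significant digits


def test_nifti_round_trip_and_3d_contract(tmp_path):
    rng = np.random.default_rng(3)
    vol = rng.normal(size=(5, 6, 7))
    save_nifti(tmp_path / "sub-01_echo-01_MEGRE.nii.gz", vol, np.eye(4))
    loaded = load_volume(tmp_path / "sub-01_echo-01_MEGRE.nii.gz")
    np.testing.assert_array_equal(loaded.voxels, vol)
    save_nifti(tmp_path / "bad.nii", rng.normal(size=(2, 2, 2, 2)), np.eye(4))
    with pytest.raises(bids_io.FormatError, match="3-D"):
        load_volume(tmp_path / "bad.nii")
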