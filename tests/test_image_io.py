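"""Frame/ROI/manifest/time-course readers and writers."""

import json

import numpy as np
import pandas as pd
import pytest
import tifffile

from nanofret.image_io import (
    ACCEPTOR,
    DONOR,
    ChannelFrame,
    FrameRecord,
    ImageIOError,
    Manifest,
    RoiSet,
    read_frame,
    read_manifest,
    read_roiset,
    read_timecourse_csv,
    write_frame,
    write_manifest,
    write_roiset,
    write_timecourse_csv,
)


def make_frame(dtype=np.uint16, value=100):
    data = np.full((8, 10), value, dtype=dtype)
    return ChannelFrame(data=data, channel=DONOR, time_h=1.0, subject="phantom-a")


class TestFrames:
    def test_round_trip_uint16(self, tmp_path):
        frame = make_frame()
        path = write_frame(frame, tmp_path / "f.tif")
        back = read_frame(path)
        assert np.array_equal(back.data, frame.data)
        assert back.data.dtype == np.uint16
        assert (back.channel, back.time_h, back.subject) == (DONOR, 1.0, "phantom-a")
        assert back.wavelength_nm == 700

    def test_round_trip_float32(self, tmp_path):
        frame = ChannelFrame(
            data=np.linspace(0, 1, 20, dtype=np.float32).reshape(4, 5),
            channel=ACCEPTOR,
            time_h=2.0,
        )
        back = read_frame(write_frame(frame, tmp_path / "f.tif"))
        assert np.array_equal(back.data, frame.data)
        assert back.wavelength_nm == 820

    def test_8bit_promoted_with_warning(self, tmp_path):
        path = tmp_path / "f.tif"
        tifffile.imwrite(path, np.full((4, 4), 7, dtype=np.uint8))
        write_frame(make_frame(), tmp_path / "meta_donor.tif")  # craft a sidecar
        (tmp_path / "f.tif.json").write_text(
            json.dumps({"channel": DONOR, "time_h": 0.0, "subject": ""})
        )
        with pytest.warns(UserWarning, match="promoted"):
            back = read_frame(path)
        assert back.data.dtype == np.uint16

    def test_rgb_rejected(self, tmp_path):
        path = tmp_path / "rgb.tif"
        tifffile.imwrite(path, np.zeros((4, 4, 3), dtype=np.uint16))
        (tmp_path / "rgb.tif.json").write_text(
            json.dumps({"channel": DONOR, "time_h": 0.0})
        )
        with pytest.raises(ImageIOError, match="separate files"):
            read_frame(path)

    def test_missing_sidecar(self, tmp_path):
        path = tmp_path / "f.tif"
        tifffile.imwrite(path, np.zeros((4, 4), dtype=np.uint16))
        with pytest.raises(ImageIOError, match="sidecar"):
            read_frame(path)

    def test_truncated_tiff_rejected(self, tmp_path):
        path = write_frame(make_frame(), tmp_path / "f.tif")
        path.write_bytes(path.read_bytes()[:40])
        with pytest.raises(ImageIOError, match="malformed"):
            read_frame(path)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(data=np.zeros((4, 4)) - 1, channel=DONOR, time_h=0.0),
            dict(data=np.zeros((0, 4)), channel=DONOR, time_h=0.0),
            dict(data=np.zeros((4, 4)), channel="green", time_h=0.0),
        ],
    )
    def test_frame_invariants(self, kwargs):
        with pytest.raises(ImageIOError):
            ChannelFrame(**kwargs)


class TestRois:
    def make_rois(self):
        mask = np.zeros((8, 10), dtype=np.uint8)
        mask[2:4, 3:7] = 1
        mask[6:8, 0:2] = 2
        return RoiSet(mask=mask, names={1: "liver", 2: "tail_vein"})

    def test_round_trip(self, tmp_path):
        rois = self.make_rois()
        write_roiset(rois, tmp_path / "m.tif", tmp_path / "m.json")
        back = read_roiset(tmp_path / "m.tif", tmp_path / "m.json")
        assert np.array_equal(back.mask, rois.mask)
        assert back.names == rois.names

    def test_shape_mismatch_detected(self, tmp_path):
        rois = self.make_rois()
        write_roiset(rois, tmp_path / "m.tif", tmp_path / "m.json")
        with pytest.raises(ImageIOError, match="shape"):
            read_roiset(tmp_path / "m.tif", tmp_path / "m.json", expect_shape=(16, 16))

    def test_unknown_label_in_names(self):
        mask = np.zeros((4, 4), dtype=np.uint8)
        mask[0, 0] = 1
        with pytest.raises(ImageIOError, match="absent"):
            RoiSet(mask=mask, names={1: "liver", 9: "ghost"})

    def test_unknown_region_lookup(self):
        with pytest.raises(ImageIOError, match="unknown region"):
            self.make_rois().region_mask("tumor")


class TestManifest:
    def build(self, tmp_path):
        for t in (0.0, 1.0):
            for ch in (DONOR, ACCEPTOR):
                frame = ChannelFrame(
                    data=np.full((8, 10), 5, dtype=np.uint16), channel=ch, time_h=t
                )
                write_frame(frame, tmp_path / f"{t:g}_{ch}.tif")
        mask = np.zeros((8, 10), dtype=np.uint8)
        mask[0, 0] = 1
        write_roiset(RoiSet(mask, {1: "liver"}), tmp_path / "rois.tif", tmp_path / "rois.json")
        records = [
            FrameRecord(path=f"{t:g}_{ch}.tif", time_h=t, channel=ch)
            for t in (0.0, 1.0)
            for ch in (DONOR, ACCEPTOR)
        ]
        return Manifest(
            scenario="demo",
            times=[0.0, 1.0],
            frames=records,
            roi_mask="rois.tif",
            roi_names="rois.json",
            seed=3,
            root=tmp_path,
        )

    def test_round_trip(self, tmp_path):
        manifest = self.build(tmp_path)
        write_manifest(manifest, tmp_path / "manifest.json")
        back = read_manifest(tmp_path / "manifest.json")
        assert back.scenario == "demo"
        assert back.times == [0.0, 1.0]
        assert back.seed == 3
        assert [f.path for f in back.frames] == [f.path for f in manifest.frames]
        assert back.load_frame(1.0, DONOR).data[0, 0] == 5

    def test_missing_frame_file_named(self, tmp_path):
        manifest = self.build(tmp_path)
        write_manifest(manifest, tmp_path / "manifest.json")
        (tmp_path / "1_donor.tif").unlink()
        back = read_manifest(tmp_path / "manifest.json")
        with pytest.raises(ImageIOError, match="1_donor.tif"):
            back.load_frame(1.0, DONOR)

    def test_times_must_increase_and_start_at_zero(self, tmp_path):
        with pytest.raises(ImageIOError, match="increasing"):
            Manifest("x", [0.0, 2.0, 1.0], [], "m.tif", "m.json")
        with pytest.raises(ImageIOError, match="pre-injection"):
            Manifest("x", [1.0, 2.0], [], "m.tif", "m.json")


class TestTimecourseCsv:
    def table(self):
        return pd.DataFrame(
            {
                "region": ["liver"] * 3,
                "quantity": ["integrity"] * 3,
                "time_h": [1.0, 2.0, 6.0],
                "value": [95.0, 88.0, 66.0],
                "sem": [1.0, 1.2, 2.0],
                "n": [3, 3, 3],
                "flags": ["", "", ""],
            }
        )

    def test_round_trip(self, tmp_path):
        path = write_timecourse_csv(self.table(), tmp_path / "tc.csv")
        back = read_timecourse_csv(path)
        assert np.allclose(back["value"], [95.0, 88.0, 66.0])

    def test_non_monotone_times_rejected(self, tmp_path):
        bad = self.table()
        bad.loc[2, "time_h"] = 1.5
        (tmp_path / "tc.csv").write_text(bad.to_csv(index=False))
        with pytest.raises(ImageIOError, match="increasing"):
            read_timecourse_csv(tmp_path / "tc.csv")

    def test_missing_column_rejected(self, tmp_path):
        with pytest.raises(ImageIOError, match="missing columns"):
            write_timecourse_csv(self.table().drop(columns=["sem"]), tmp_path / "tc.csv")
        (tmp_path / "tc.csv").write_text(self.table().drop(columns=["value"]).to_csv(index=False))
        with pytest.raises(ImageIOError, match="missing columns"):
            read_timecourse_csv(tmp_path / "tc.csv")
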