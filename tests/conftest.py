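import numpy as np
import pytest

from stochlung import (EngineConfig, Maneuver, SubjectLungFunction,
                       device_preset)
from stochlung import study


@pytest.fixture(scope="session")
def control_lungs() -> SubjectLungFunction:
    lv = study.group_mean_lung_volumes("Control")
    return SubjectLungFunction(rv=lv["rv"], tlc=lv["tlc"], frc=lv["frc"],
                               group="Control", subject_id="C-mean")


@pytest.fixture(scope="session")
def control_pmdi_maneuver() -> Maneuver:
    mm = study.group_mean_maneuver("Control", "Foster_pMDI")
    return Maneuver(ivc_d=mm["ivc_d"], pif_d=mm["pif_d"], t_in=mm["t_in"],
                    t_bh=mm["t_bh"], device="Foster_pMDI")


@pytest.fixture(scope="session")
def pmdi_spec():
    return device_preset("Foster_pMDI")


@pytest.fixture(scope="session")
def engine_config() -> EngineConfig:
    return EngineConfig()


def group_maneuver(group: str, device: str) -> Maneuver:
    mm = study.group_mean_maneuver(group, device)
    return Maneuver(ivc_d=mm["ivc_d"], pif_d=mm["pif_d"], t_in=mm["t_in"],
                    t_bh=mm["t_bh"], device=device)


def group_lungs(group: str) -> SubjectLungFunction:
    lv = study.group_mean_lung_volumes(group)
    return SubjectLungFunction(rv=lv["rv"], tlc=lv["tlc"], frc=lv["frc"],
                               group=group, subject_id=f"{group}-mean")
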