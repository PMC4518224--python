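import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dynamap.core import OdeModel
from dynamap.library import get_model

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=30,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def goodwin_model():
    return get_model("goodwin")


@pytest.fixture(scope="session")
def pfb_model():
    return get_model("pfb2")


@pytest.fixture(scope="session")
def mixed_model():
    return get_model("mixed")


@pytest.fixture(scope="session")
def multisite_model():
    return get_model("multisite")


@pytest.fixture(scope="session")
def linear_decay_model():
    """1-state fixture dx/dt = -k*x with known Jacobian (-k)."""

    def rhs(x, p):
        return -p["k"] * x

    def jac(x, p):
        out = np.zeros(x.shape[:-1] + (1, 1))
        out[..., 0, 0] = -p["k"]
        return out

    return OdeModel(
        name="linear_decay",
        state_names=("x",),
        param_names=("k",),
        rhs=rhs,
        jacobian=jac,
        state_upper_bounds=lambda p: np.array([10.0]),
        default_params={"k": 1.0},
    )


GOODWIN_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version2/core" level="3" version="2">
 <model id="goodwin_loop">
  <listOfCompartments>
   <compartment id="cell" size="1" constant="true"/>
  </listOfCompartments>
  <listOfSpecies>
   <species id="S1" compartment="cell" initialConcentration="0.1" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
   <species id="S2" compartment="cell" initialConcentration="0.1" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
   <species id="S3" compartment="cell" initialConcentration="0.1" constant="false" boundaryCondition="false" hasOnlySubstanceUnits="false"/>
  </listOfSpecies>
  <listOfParameters>
   <parameter id="k1" value="0.1" constant="true"/>
   <parameter id="k2" value="0.1" constant="true"/>
   <parameter id="k3" value="0.1" constant="true"/>
   <parameter id="kd1" value="0.01" constant="true"/>
   <parameter id="kd2" value="0.01" constant="true"/>
   <parameter id="kd3" value="0.01" constant="true"/>
   <parameter id="K" value="1" constant="true"/>
   <parameter id="n" value="9" constant="true"/>
  </listOfParameters>
  <listOfReactions>
   <reaction id="syn1" reversible="false">
    <listOfProducts>
     <speciesReference species="S1" stoichiometry="1" constant="true"/>
    </listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><divide/>
       <apply><times/><ci>k1</ci><apply><power/><ci>K</ci><ci>n</ci></apply></apply>
       <apply><plus/>
        <apply><power/><ci>K</ci><ci>n</ci></apply>
        <apply><power/><ci>S3</ci><ci>n</ci></apply>
       </apply>
      </apply>
     </math>
    </kineticLaw>
   </reaction>
   <reaction id="deg1" reversible="false">
    <listOfReactants>
     <speciesReference species="S1" stoichiometry="1" constant="true"/>
    </listOfReactants>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>kd1</ci><ci>S1</ci></apply>
     </math>
    </kineticLaw>
   </reaction>
   <reaction id="syn2" reversible="false">
    <listOfProducts>
     <speciesReference species="S2" stoichiometry="1" constant="true"/>
    </listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>k2</ci><ci>S1</ci></apply>
     </math>
    </kineticLaw>
   </reaction>
   <reaction id="deg2" reversible="false">
    <listOfReactants>
     <speciesReference species="S2" stoichiometry="1" constant="true"/>
    </listOfReactants>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>kd2</ci><ci>S2</ci></apply>
     </math>
    </kineticLaw>
   </reaction>
   <reaction id="syn3" reversible="false">
    <listOfProducts>
     <speciesReference species="S3" stoichiometry="1" constant="true"/>
    </listOfProducts>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>k3</ci><ci>S2</ci></apply>
     </math>
    </kineticLaw>
   </reaction>
   <reaction id="deg3" reversible="false">
    <listOfReactants>
     <speciesReference species="S3" stoichiometry="1" constant="true"/>
    </listOfReactants>
    <kineticLaw>
     <math xmlns="http://www.w3.org/1998/Math/MathML">
      <apply><times/><ci>kd3</ci><ci>S3</ci></apply>
     </math>
    </kineticLaw>
   </reaction>
  </listOfReactions>
 </model>
</sbml>
"""


@pytest.fixture()
def goodwin_sbml_path(tmp_path):
    p = tmp_path / "goodwin.xml"
    p.write_text(GOODWIN_SBML)
    return p
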