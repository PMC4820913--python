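<?xml version="1.0" encoding="UTF-8"?>
<!-- Hand-authored reader fixture: A -> B -> C, mass action. -->
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="two_step_pathway" name="Two step pathway">
    <listOfCompartments>
      <compartment id="cytosol" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cytosol" initialAmount="10"/>
      <species id="B" compartment="cytosol" initialAmount="0"/>
      <species id="C" compartment="cytosol" initialAmount="0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k1" value="0.3"/>
      <parameter id="k2" value="0.1"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="step1" reversible="false">
        <listOfReactants>
          <speciesReference species="A"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <times/>
              <ci>k1</ci>
              <ci>A</ci>
            </apply>
          </math>
        </kineticLaw>
      </reaction>
      <reaction id="step2" reversible="false">
        <listOfReactants>
          <speciesReference species="B"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="C"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <times/>
              <ci>k2</ci>
              <ci>B</ci>
            </apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
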