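<?xml version="1.0" encoding="UTF-8"?>
<!-- Hand-authored fixture: a function definition that the reader must
     expand inline into the kinetic law at read time. -->
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="function_def_model">
    <listOfFunctionDefinitions>
      <functionDefinition id="mm">
        <math xmlns="http://www.w3.org/1998/Math/MathML">
          <lambda>
            <bvar><ci>v</ci></bvar>
            <bvar><ci>k</ci></bvar>
            <bvar><ci>s</ci></bvar>
            <apply>
              <divide/>
              <apply><times/><ci>v</ci><ci>s</ci></apply>
              <apply><plus/><ci>k</ci><ci>s</ci></apply>
            </apply>
          </lambda>
        </math>
      </functionDefinition>
    </listOfFunctionDefinitions>
    <listOfCompartments>
      <compartment id="cell" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="S" compartment="cell" initialAmount="4"/>
      <species id="P" compartment="cell" initialAmount="0"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="Vm" value="10"/>
      <parameter id="Km" value="2"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="conv" reversible="false">
        <listOfReactants>
          <speciesReference species="S"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="P"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <ci>mm</ci>
              <ci>Vm</ci>
              <ci>Km</ci>
              <ci>S</ci>
            </apply>
          </math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
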