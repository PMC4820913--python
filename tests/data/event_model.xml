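<?xml version="1.0" encoding="UTF-8"?>
<!-- Hand-authored fixture: contains an event, which the reader must
     reject loudly (events are outside the supported subset). -->
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="event_model">
    <listOfCompartments>
      <compartment id="cell" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialAmount="1"/>
    </listOfSpecies>
    <listOfEvents>
      <event id="reset">
        <trigger>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply><gt/><ci>A</ci><cn>5</cn></apply>
          </math>
        </trigger>
      </event>
    </listOfEvents>
  </model>
</sbml>
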