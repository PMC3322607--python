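<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="qualified">

  <xs:simpleType name="pct">
    <xs:restriction base="xs:decimal">
      <xs:minInclusive value="0"/>
      <xs:maxInclusive value="100"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:complexType name="scoreBlock">
    <xs:attribute name="id" type="xs:string"/>
    <xs:attribute name="rama_outlier_pct" type="pct"/>
    <xs:attribute name="rotamer_outlier_pct" type="pct"/>
    <xs:attribute name="clashscore" type="xs:decimal"/>
    <xs:attribute name="rsrz_outlier_pct" type="pct"/>
    <xs:attribute name="mean_rsr" type="xs:decimal"/>
    <xs:attribute name="n_rama_evaluated" type="xs:nonNegativeInteger"/>
    <xs:attribute name="n_rotamer_evaluated" type="xs:nonNegativeInteger"/>
    <xs:attribute name="n_rsrz_evaluated" type="xs:nonNegativeInteger"/>
    <xs:attribute name="n_atoms" type="xs:nonNegativeInteger"/>
  </xs:complexType>

  <xs:element name="validation_report">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="summary">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="entry" type="scoreBlock"/>
              <xs:element name="chain" type="scoreBlock"
                          minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="data_checks" minOccurs="0">
          <xs:complexType>
            <xs:attribute name="r" type="xs:decimal"/>
            <xs:attribute name="r_free" type="xs:decimal"/>
            <xs:attribute name="scale_k" type="xs:decimal"/>
            <xs:attribute name="wilson_b" type="xs:decimal"/>
            <xs:attribute name="moment_ratio" type="xs:decimal"/>
            <xs:attribute name="mislabel_verdict" type="xs:string"/>
            <xs:attribute name="l_mean" type="xs:decimal"/>
            <xs:attribute name="l_second" type="xs:decimal"/>
            <xs:attribute name="twin_verdict" type="xs:string"/>
            <xs:attribute name="n_outlier_reflections"
                          type="xs:nonNegativeInteger"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="percentiles" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="metric" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                  <xs:attribute name="ranked" type="xs:boolean"/>
                  <xs:attribute name="raw" type="xs:decimal"/>
                  <xs:attribute name="absolute" type="pct"/>
                  <xs:attribute name="relative" type="pct"/>
                  <xs:attribute name="cohort" type="xs:nonNegativeInteger"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="archive_version" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="chains">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="chain" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="residue" minOccurs="0"
                                maxOccurs="unbounded">
                      <xs:complexType>
                        <xs:attribute name="name" type="xs:string"
                                      use="required"/>
                        <xs:attribute name="seq" type="xs:integer"
                                      use="required"/>
                        <xs:attribute name="icode" type="xs:string"/>
                        <xs:attribute name="rama" type="xs:string"/>
                        <xs:attribute name="rotamer" type="xs:string"/>
                        <xs:attribute name="rotamer_dev" type="xs:decimal"/>
                        <xs:attribute name="rsr" type="xs:decimal"/>
                        <xs:attribute name="rsrz" type="xs:decimal"/>
                        <xs:attribute name="geom_max_z" type="xs:decimal"/>
                        <xs:attribute name="clashes"
                                      type="xs:nonNegativeInteger"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:sequence>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="resolution" type="xs:decimal"/>
      <xs:attribute name="tool_version" type="xs:string" use="required"/>
      <xs:attribute name="archive_version" type="xs:string"/>
      <xs:attribute name="config_hash" type="xs:string"/>
      <xs:attribute name="seed" type="xs:integer"/>
      <xs:attribute name="schema_version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
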