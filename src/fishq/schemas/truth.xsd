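<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="truth">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="nucleus" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="spot" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="channel" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="FITC"/>
                        <xs:enumeration value="RHODAMINE"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                  <xs:attribute name="row" type="xs:double" use="required"/>
                  <xs:attribute name="col" type="xs:double" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:positiveInteger" use="required"/>
            <xs:attribute name="row" type="xs:double" use="required"/>
            <xs:attribute name="col" type="xs:double" use="required"/>
            <xs:attribute name="radius_px" type="xs:double" use="required"/>
            <xs:attribute name="red" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="green" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="class" use="required">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="normal"/>
                  <xs:enumeration value="amplified"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
            <xs:attribute name="sharp_plane" type="xs:nonNegativeInteger" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="core_id" type="xs:string" use="required"/>
      <xs:attribute name="n_nuclei" type="xs:nonNegativeInteger" use="required"/>
      <xs:attribute name="n_normal" type="xs:nonNegativeInteger" use="required"/>
      <xs:attribute name="n_amplified" type="xs:nonNegativeInteger" use="required"/>
      <xs:attribute name="total_red" type="xs:nonNegativeInteger" use="required"/>
      <xs:attribute name="total_green" type="xs:nonNegativeInteger" use="required"/>
      <xs:attribute name="seed" type="xs:long" use="required"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
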