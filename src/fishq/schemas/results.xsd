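<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">
  <xs:element name="fishquant">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="core" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="nucleus" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:positiveInteger" use="required"/>
                  <xs:attribute name="cx" type="xs:double" use="required"/>
                  <xs:attribute name="cy" type="xs:double" use="required"/>
                  <xs:attribute name="area" type="xs:double" use="required"/>
                  <xs:attribute name="circularity" type="xs:double" use="required"/>
                  <xs:attribute name="red" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="green" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="class" use="required">
                    <xs:simpleType>
                      <xs:restriction base="xs:string">
                        <xs:enumeration value="normal"/>
                        <xs:enumeration value="amplified"/>
                        <xs:enumeration value="artifact"/>
                      </xs:restriction>
                    </xs:simpleType>
                  </xs:attribute>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string" use="required"/>
            <xs:attribute name="n_detected" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="n_normal" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="n_amplified" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="n_artifact" type="xs:nonNegativeInteger" use="required"/>
            <xs:attribute name="std40_normal" type="xs:double"/>
            <xs:attribute name="std40_amplified" type="xs:double"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
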